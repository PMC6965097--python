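{
 "segment_order": [
  "top",
  "top_right",
  "bottom_right",
  "bottom",
  "bottom_left",
  "top_left",
  "mid_left",
  "mid_right",
  "diag_tl",
  "vert_top",
  "diag_tr",
  "diag_bl",
  "vert_bot",
  "diag_br"
 ],
 "codes": {
  "A": "11101111000000",
  "B": "11110011010010",
  "C": "10011100000000",
  "D": "11110000010010",
  "E": "10011111000000",
  "F": "10001111000000",
  "G": "10111101000000",
  "H": "01101111000000",
  "I": "10010000010010",
  "J": "11111000000000",
  "K": "00001110001001",
  "L": "00011100000000",
  "M": "01101100101000",
  "N": "01101100100001",
  "O": "11111100000000",
  "P": "11001111000000",
  "Q": "11111100000001",
  "R": "11001111000001",
  "S": "10110111000000",
  "T": "10000000010010",
  "U": "01111100000000",
  "V": "00001100001100",
  "W": "01101100000101",
  "X": "00000000101101",
  "Y": "00000000101010",
  "Z": "10010000001100",
  "0": "11111100001100",
  "1": "00000000010010",
  "2": "11011011000000",
  "3": "11110001000000",
  "4": "01100111000000",
  "5": "10010111000001",
  "6": "10111111000000",
  "7": "11100000000010",
  "8": "11111111000000",
  "9": "11110111000000"
 }
}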