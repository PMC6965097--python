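"""Fourteen-segment glyph encoding of alphanumeric characters.

Characters are rendered in a segmented font in which every one of the 36
alphanumeric characters (A-Z, 0-9) is composed from 14 strokes.  The encoding
function ``phi(c)`` maps a character to a binary vector of length 14 marking
which strokes are on.  Five-character strings are encoded by concatenating the
five glyph vectors into a single 70-dimensional feature vector, the input of
the letter-recognition network.

The default font is shipped as an editable JSON asset
(``assets/fourteen_segment_font.json``); alternative fonts can be loaded from
any JSON file with the same layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

N_SEGMENTS = 14
N_CHARS = 36
STRING_LENGTH = 5
N_FEATURES = N_SEGMENTS * STRING_LENGTH


@dataclass(frozen=True)
class GlyphTable:
    """Map from 36 alphanumeric characters to binary 14-segment codes.

    Attributes
    ----------
    chars : tuple of str
        The 36 characters, in a fixed order that also defines letter-unit
        ordering inside network layers.
    codes : ndarray of shape (36, 14)
        Binary (0/1) segment codes, one row per character.
    """

    chars: tuple
    codes: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        chars = tuple(self.chars)
        codes = np.asarray(self.codes, dtype=float)
        if len(chars) != N_CHARS:
            raise ValueError(f"glyph table must have exactly {N_CHARS} characters, got {len(chars)}")
        if codes.shape != (N_CHARS, N_SEGMENTS):
            raise ValueError(f"codes must have shape ({N_CHARS}, {N_SEGMENTS}), got {codes.shape}")
        if not np.isin(codes, (0.0, 1.0)).all():
            raise ValueError("glyph codes must be binary")
        if len({tuple(row) for row in codes.astype(int)}) != N_CHARS:
            raise ValueError("glyph codes must be pairwise distinct")
        if len(set(chars)) != N_CHARS:
            raise ValueError("characters must be unique")
        object.__setattr__(self, "chars", chars)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(chars)})

    def index(self, char: str) -> int:
        try:
            return self._index[char]
        except KeyError:
            raise KeyError(f"character {char!r} is not in the glyph table") from None

    def phi(self, char: str) -> np.ndarray:
        """Binary 14-segment feature vector of ``char``."""
        return self.codes[self.index(char)].copy()

    def encode_string(self, s: str) -> np.ndarray:
        """Encode a five-character string as a 70-dimensional binary vector.

        The result is the concatenation ``phi(s[0]) || ... || phi(s[4])``.
        """
        if len(s) != STRING_LENGTH:
            raise ValueError(f"expected a string of length {STRING_LENGTH}, got {s!r} (length {len(s)})")
        return np.concatenate([self.phi(c) for c in s])

    @classmethod
    def from_json(cls, path=None) -> "GlyphTable":
        """Load a glyph table from a JSON asset.

        The JSON must map each character to a 14-character ``'0'/'1'`` string
        under the key ``codes``.  With no ``path``, the packaged default
        fourteen-segment font is used.
        """
        if path is None:
            raw = resources.files("lexnet.assets").joinpath("fourteen_segment_font.json").read_text()
            data = json.loads(raw)
        else:
            with open(path) as fh:
                data = json.load(fh)
        chars = tuple(sorted(data["codes"], key=_char_order))
        codes = np.array([[int(b) for b in data["codes"][c]] for c in chars], dtype=float)
        return cls(chars, codes)


def _char_order(c: str):
    # letters first (A-Z), then digits (0-9)
    return (c.isdigit(), c)


_DEFAULT = None


def default_glyph_table() -> GlyphTable:
    """The packaged fourteen-segment font (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = GlyphTable.from_json()
    return _DEFAULT


def encode_string(s: str, glyphs: GlyphTable | None = None) -> np.ndarray:
    """Encode a five-character string with ``glyphs`` (default packaged font)."""
    return (glyphs or default_glyph_table()).encode_string(s)
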