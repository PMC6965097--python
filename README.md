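# lexnet

Predictive-coding simulation of word-context effects on letter recognition,
plus a synthetic-fMRI analysis pipeline for letter information in visual
cortex: trial-wise letter decoding, split-half pattern-correlation
information, a univariate amplitude control, and information–activation
coupling with AR(1)-prewhitened GLMs and permutation-based group inference.

The package has two halves that meet in the middle:

1. **Simulator** (`lexnet.iam`, `lexnet.glyphs`): a two-stage hierarchical
   network (letter units over five string slots, word units with
   word-to-letter feedback) implemented with divisive-input-modulation
   predictive coding. Comparing a top-down configuration (feedback gain 0.4)
   against a feedback-severed one (gain 10⁻⁶) isolates the word-superiority
   effect: noisy middle letters are recovered better inside words than
   inside matched nonwords only when feedback is intact.
2. **Synthetic fMRI pipeline** (`lexnet.synth`, `lexnet.mvpa`,
   `lexnet.coupling`, `lexnet.stats`, `lexnet.pipeline`): generators with
   recorded ground truth produce localiser patterns, BOLD sessions and
   coupling timecourses; the analysis side must recover the implanted
   effects and stay calibrated on null data.

## Worked example

```python
import numpy as np
from lexnet import iam

# Scaled word-superiority simulation: 1000-word vocabulary, 10 runs of
# 96 noisy five-letter stimuli (words vs consonant-string nonwords with
# matched middle letters U/N), two models differing only in feedback gain.
vocab = iam.default_lexicon()
rng = np.random.default_rng(0)
t_u = iam.make_nonwords(vocab, rng, 1, middle="U")[0]
t_n = iam.make_nonwords(vocab, rng, 1, middle="N")[0]
vocab = iam.Vocabulary(tuple(sorted(vocab.words + (t_u, t_n))),
                       vocab.letter_frequencies)
words_u = [w for w in vocab.words if w[2] == "U"]
words_n = [w for w in vocab.words if w[2] == "N"]
pool = (iam.make_nonwords(vocab, rng, 60, middle="U")
        + iam.make_nonwords(vocab, rng, 60, middle="N"))
runs = [iam.make_stimulus_run(vocab, pool, (words_u[0], words_n[0]),
                              (t_u, t_n), rng) for _ in range(10)]
results, extra = iam.simulate_experiment(vocab, runs)
print(extra["stats"]["top_down"])     # t ≈ 8.44, p ≈ 1.4e-5
print(extra["stats"]["feedforward"])  # t ≈ 0.37, p ≈ 0.72
```

Output (seed 0): the top-down model shows a strong word advantage in
middle-letter relative evidence (paired *t* = 8.44 across runs, mean
difference 0.057), the feedback-severed model shows none (*t* = 0.37), and
the interaction *t* is 5.04. Over 20 seeds, top-down *t* > 5 in 20/20 replicates (minimum 7.9,
median 11.0) and feedforward |*t*| < 2 in 20/20. Luce middle-letter response
accuracy exceeds 99% in all four letter × context cells, and noiseless word
recognition is 100%.

The full synthetic pipeline runs with one command:

```bash
lexnet full-run --seed 0 --out out/
cat out/report.json
```

With the default configuration (16 participants, 300 voxels, enhancement
g = 1.5, coupling slopes 1.0 vs 0.5) all three detections fire — word >
nonword decoding, word > nonword pattern information, positive group
coupling difference — and the exit status is 0. Re-running with the same
config produces a byte-identical `report.json`.

Representative numbers from the calibration and recovery studies
(`python scripts/acceptance.py --seed 0 --out report.json`, ~2 minutes):

| Quantity | Value |
| --- | --- |
| Null decoding accuracy (100 sessions, no letter signal) | 50.6% |
| Null pattern-info 95% interval | [−0.056, 0.079] |
| Recovery at g = 1.5: word > nonword decoding / info | 50/50 and 50/50 seeds |
| Overall decoding at g = 1.5, top-200 voxels | 84.6% |
| Amplitude control at g = 1.5 | diff ≈ −0.0004, p ≈ 0.57 |
| ROI coupling type-I rate (200 null cohorts, α = 0.05) | 0.045 |
| Coupling slope-difference recovery (true 0.5) | 0.509 (bias +1.8%) |
| Voxelwise sign-flip cluster FWER (50 null datasets) | 0.00 |

## Command-line interface

```
lexnet simulate   --seed N --runs R --out DIR      # word-superiority simulation
lexnet synthesize --seed N --n-voxels V --out DIR  # synthetic participant fixtures
lexnet mvpa       --localiser TSV --main TSV --out DIR
lexnet coupling   --evidence TSV --target TSV --motion TSV --out DIR
lexnet full-run   [--config FILE] [--seed N] --out DIR
```

Every command logs to stderr and `DIR/lexnet.log` and stamps its JSON
outputs with the seed (and config hash where applicable).

## Tests

```bash
python -m pytest            # full suite, includes tests/test_acceptance.py
python scripts/acceptance.py --seed 0 --out report.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(simulator dissociation, full-scale simulation, Luce accuracy, MVPA null
calibration, MVPA recovery with amplitude control, coupling calibration and
recovery, deterministic invariants). `docs/methods.md` documents the methods
and the generator calibration.
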