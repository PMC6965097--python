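# Methods

This note documents the models, analyses and generator calibrations
implemented in `lexnet`, in enough detail to re-derive every default.

## 1. Interactive-activation simulator (`lexnet.iam`, `lexnet.glyphs`)

### Stimulus encoding

Stimuli are five-character strings over a 36-character alphabet (A–Z, 0–9).
Each character is a binary 14-segment glyph; a string is the concatenation
of its five glyph vectors (70 features). The packaged font
(`assets/fourteen_segment_font.json`) has 36 unique codes; alternative fonts
load via `GlyphTable.from_json`.

### Network dynamics

Both stages are divisive-input-modulation predictive-coding circuits with
prediction units `y`, error units `e` and a reconstruction `r`:

```
e = x ⊘ max(r, ε₂)
y ← max(y, ε₁) ⊗ (W e)
r = V y
```

with ε₁ = 10⁻⁶, ε₂ = 10⁻³, elementwise multiply/divide, zero
initialisation, and 60 update sweeps per stimulus batch. Each sweep updates
the letter stage on the current feedback, then the word stage on the fresh
letter activations. When the reconstruction equals a supra-threshold input,
the error units sit at the fixed point `e = 1`.

Inputs are corrupted by additive Gaussian noise (σ = 0.125) clipped at
zero. Readouts: the relative evidence `q` of a slot's correct letter unit
(its activation over the 36-unit slot sum) and a Luce/softmax response rule
with inverse temperature β = 10 applied to the middle-letter slot.

### Architecture

**Letter stage** (180 units = 5 slots × 36 characters, 250 inputs = 70
features + 180 feedback channels). Feedforward weights are the slot-local
glyph codes, row-normalised so every unit's glyph weights sum to 1 (mean
evidence per stroke; this keeps sparse and dense glyphs comparable).
Feedback weights are `g·I`, with `g = 0.4` (top-down) or `10⁻⁶`
(feedback-severed control). The reconstruction matrix is the gain-free
`V = [ff | I]ᵀ`: the error computation on the feedback channels then
divides by `max(y, ε₂)`, so a severed gain (`g·y ≪ ε₂`) suppresses the
feedback contribution by construction while an intact gain lets word
predictions bias the letter competition. `V` is deliberately not
column-normalised; halving it doubles the error signal and with it the
effective feedback drive, which reintroduces lexical capture of nonwords
(verified empirically).

**Word stage** (vocabulary units + 180 single-character units, 180 inputs).
Each word row places uniform weight on its five (slot, letter) units and is
row-normalised to 1/5 per entry. Uniform (rather than frequency-weighted)
entries make the worst-case "attacker" bound exact: a word matching 4 of 5
letters of the input reaches at most 0.8 of a full match. The 180
single-character rows are `c·I` with `c = 0.88 ∈ (0.8, 1)`: any letter
also explained by a fully matching word loses to that word (0.88 < 1.0),
so feedback still flows on word trials, while letters inside nonwords are
claimed by their character unit (0.88 > 0.8), which blocks partial-match
words from capturing nonword inputs. `V` is the column-wise sum-normalised
transpose. Word recognition reads out the argmax over word units.

Under this architecture, over 20 fixed seeds (1000-word vocabulary, 10
runs): top-down paired *t* > 5 in 20/20 replicates (min 7.9), severed
|*t*| < 2 in 20/20 (max 1.99), interaction *t* ≥ 4.4, Luce accuracy > 99%
in all letter × context cells, and noiseless recognition is exact.

### Materials and experiment

The packaged 1007-word five-letter English lexicon (≥ 48 members each with
middle letter U and N) is the stand-in vocabulary; `sample_vocabulary`
generates arbitrary-size stand-ins from positional letter frequencies.
Nonwords draw letters i.i.d. from the lexicon's letter frequencies with no
adjacent repeats, fewer than two vowels, and no lexicon membership. A run
presents 48 words and 48 nonwords (middle letters U/N balanced 24/24), with
12% targets. `simulate_experiment` presents identical noise realisations to
both models, aggregates `q` per run × model × condition, and reports paired
t-tests per model plus a two-sample interaction t-test on the per-run
word−nonword differences.

## 2. MVPA (`lexnet.mvpa`)

Preprocessing per run: Savitzky–Golay smoothing (order 3, window 21 TRs;
exact on cubic trends), per-voxel z-scoring (zero-variance voxels → 0 with
a warning), a 3-TR label shift compensating haemodynamic lag (TR = 1.4 s),
and averaging the 10 TRs of each 14-s trial.

Decoding: L2-regularised logistic regression (library defaults) trained on
localiser patterns (single letters), tested trial-wise on the main
experiment per context condition. Voxel selection: top-k (default k = 200)
by absolute two-sample t between the letters, ties broken by lowest index;
or a "peripheral" mode intersecting the top half of main-experiment
statistics with the bottom half of localiser statistics.

Pattern information: over 12 random split-halves, cell patterns (letter ×
context) are averaged per half; the score is the mean same-letter
cross-half correlation minus the mean different-letter cross-half
correlation, per context condition.

Classifier evidence: the per-TR probability assigned to the letter actually
presented (complement for the second letter), NaN on null TRs; this is the
seed of the coupling analysis.

Searchlight: spheres of 6 mm Euclidean radius on a labelled voxel grid
(2 mm spacing → 123 voxels in a full sphere), scoring either decoding
accuracy or pattern information at the centre voxel.

Amplitude control: per-run GLM of the voxel-mean timecourse on
HRF-convolved condition boxcars plus intercept; run betas combined as an
unweighted mean. Rank-deficient designs are refused with the offending
columns named.

## 3. Information–activation coupling (`lexnet.coupling`)

The design has 29 columns: condition-exclusive word/nonword evidence
regressors, their first-difference temporal derivatives, 24 motion
regressors (6 parameters, squares, one-TR lags, lagged squares), and an
intercept (optionally one per run). Null TRs are dropped after the temporal
operations. Fits use AR(1) prewhitening: ρ estimated from the lag-1
autocorrelation of OLS residuals, rows transformed `v_t − ρ·v_{t−1}` with
the first row scaled by √(1 − ρ²); at least 30 TRs are required. ROI-level
group inference feeds the per-participant slope pairs to the test-selection
gate (§4). Voxelwise group inference uses one-sample t → z maps, cluster
forming at z > 3.1 with face connectivity, and a sign-flip
max-cluster-extent permutation null (default 1000 permutations;
`p = (1 + #null ≥ size) / (1 + n_perm)`); groups under 8 participants are
refused.

## 4. Group statistics (`lexnet.stats`)

Paired comparisons pass a test-selection gate: D'Agostino–Pearson normality
on the differences and a 1.5 × IQR outlier check. Both clean → paired t
with Cohen's d (n−1 SD); otherwise Wilcoxon signed-rank with the
matched-pairs rank-biserial correlation `r = 1 − 2T/S` (T = rank sum of
negative differences among nonzero differences, S = n(n+1)/2). All-zero
differences are flagged degenerate. Behavioural comparisons keep the first
response per participant × trial, discard responses faster than 100 ms, and
compare per-participant median RT and mean accuracy through the same gate.

## 5. Synthetic-data generators (`lexnet.synth`)

Ground truth per dataset: one standard-normal template per letter and
voxel (scaled by `letter_contrast`; 0 gives a null dataset), a word-trial
enhancement factor `g` multiplying the letter template, trial noise SD,
AR(1) coefficient, coupling slopes `b_word`/`b_nonword`, and per-condition
BOLD amplitudes (equal by default, so information can differ without an
amplitude difference).

**Noise calibration.** `DEFAULT_NOISE_SD = 9.0` was fixed a priori from
the SNR convention SNR = ‖template contrast‖ / noise SD: with standard
normal templates the U−N contrast norm over the default 1000-voxel ROI is
√(2·1000) ≈ 44.7, giving SNR ≈ 5.0 over the full ROI and a trial-wise
linear-readout d′ ≈ 2.2 on the selected 200-voxel ROI, i.e. nominal
decoding in the low–mid 80s %. Observed: 84.6% overall at g = 1.5
(mean over 50 seeds), against 50.6% on null data — matching the intended
"decodable but noisy" regime. The value was not adjusted after the
acceptance studies were defined.

Sessions: 6 runs × 40 trials, each trial 10 TRs (14 s), in blocks of five
(four letter × context cells plus one null, shuffled), i.e. 48 trials per
cell and 96 per context condition; the localiser is one run of 18 trials
per letter plus 4 nulls. BOLD voxel signal: HRF-convolved boxcar (double
gamma, peak 6 s, undershoot 16 s, ratio 1/6) scaled by
`amplitude[condition] + g·template/noise_sd`, plus AR(1) noise; motion is a
smoothed 6-parameter random walk. Coupling series:
`y = b_condition · evidence + AR(1) noise` (SD 0.5). Visual noise patches:
per trial, 5 pixelwise N(128, 50²) patches plus their polarity inversions
about 128, ordered with no inversion adjacent to its original, so every
pixel's trial mean is exactly 128.

## 6. Pipeline (`lexnet.pipeline`, `lexnet.cli`)

`full_synthetic_run` executes simulator → cohort generation → MVPA +
amplitude control + coupling → group tests, writes `config.json`,
`report.json` (with schema tag, config hash and seed) and the simulator
results table. The report's checks compare the three detections (p < α and
positive direction for decoding, pattern information, coupling) against the
generating configuration's ground truth; the CLI exit status is 0 only if
they match. Reports are byte-identical across re-runs of the same
configuration (runtimes go to the log only). Calibration at the defaults:
ROI coupling type-I rate 0.045 over 200 null cohorts, slope-difference
recovery bias +1.8% (true difference 0.5), voxelwise cluster FWER 0 over
50 null group datasets.
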