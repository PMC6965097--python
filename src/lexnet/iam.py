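"""Predictive-coding interactive-activation model of five-letter word recognition.

The model is a two-stage hierarchy in the PC/BC-DIM family (Predictive Coding /
Biased Competition with Divisive Input Modulation).  Each stage holds
prediction units ``y``, error units ``e`` and a reconstruction ``r`` of its
input, updated by three rules:

    e = x / max(r, eps2)          (divisive prediction error)
    y <- max(y, eps1) * (W @ e)   (multiplicative prediction update)
    r = V @ y                     (linear generative reconstruction)

where ``W`` holds nonnegative feedforward weights and ``V`` holds nonnegative
feedback (reconstruction) weights derived from ``W``.  The first stage maps 70
visual features (5 slots x 14 strokes) onto 180 letter-position units (5 slots
x 36 characters); the second maps letter-position units onto word units plus
180 single-character units that let isolated letters be explained without
lexical support.  The word
stage's reconstruction of the letter units is fed back to the letter stage as
additional input, with a scalar gain on the feedback weights controlling
top-down strength: 0.4 in the top-down model, 1e-6 in the feedforward control
(which severs feedback in all but name).

Representational strength of a letter is summarised by its *relative
evidence*: the activation of the correct letter unit divided by the summed
activation of the 36 letter units at that slot.  Overt responses follow Luce's
choice rule (a softmax with inverse temperature ``beta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .glyphs import (
    GlyphTable,
    N_CHARS,
    N_FEATURES,
    STRING_LENGTH,
    default_glyph_table,
    encode_string,
)

N_LETTER_UNITS = N_CHARS * STRING_LENGTH  # 180
MIDDLE_SLOT = 2  # third letter position, 0-based


@dataclass(frozen=True)
class NetworkConfig:
    """Constants of the network and the simulation protocol.

    ``epsilon1``/``epsilon2`` clamp the update rules away from zero;
    ``feedback_gain`` scales the word-to-letter feedback weights (0.4 in the
    top-down model, 1e-6 in the feedforward control); ``noise_sigma`` and
    ``noise_mu`` parameterise the Gaussian feature noise added to stimulus
    encodings; ``beta`` is the inverse temperature of Luce's response rule.
    """

    epsilon1: float = 1e-6
    epsilon2: float = 1e-3
    feedback_gain: float = 0.4
    n_iterations: int = 60
    noise_sigma: float = 0.125
    noise_mu: float = 0.0
    beta: float = 10.0

    def __post_init__(self):
        for name in ("epsilon1", "epsilon2", "feedback_gain", "noise_sigma", "beta"):
            if getattr(self, name) < 0 or (name != "noise_sigma" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be strictly positive" if name != "noise_sigma" else f"{name} must be nonnegative")
        if self.noise_mu < 0:
            raise ValueError("noise_mu must be nonnegative")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")


TOP_DOWN = NetworkConfig(feedback_gain=0.4)
FEEDFORWARD = NetworkConfig(feedback_gain=1e-6)


@dataclass
class LayerState:
    """One PC/BC-DIM stage: weights plus current activations.

    ``W`` is the (units x inputs) feedforward matrix; ``V`` the (inputs x
    units) feedback matrix, equal to ``W.T`` with each column rescaled to sum
    to one (all-zero columns stay zero).  ``y``, ``e`` and ``r`` may be
    vectors or (units x batch) matrices when several stimuli are processed in
    parallel.
    """

    W: np.ndarray
    V: np.ndarray
    y: np.ndarray
    e: np.ndarray
    r: np.ndarray

    @classmethod
    def from_weights(cls, W: np.ndarray, V: np.ndarray | None = None,
                     batch: int | None = None) -> "LayerState":
        """Build a stage from feedforward weights.

        If ``V`` is not given it is derived as ``W.T`` with each column
        rescaled to sum to one (equivalently, each unit's reconstruction
        weights are its feedforward weights normalised to unit sum; all-zero
        rows stay zero).  Passing ``V`` explicitly supports stages whose
        feedback weights are derived from a rescaled copy of ``W`` (the
        letter stage builds ``V`` from gain-free feedback weights so the
        feedback gain controls drive without rescaling reconstruction).
        """
        W = np.asarray(W, dtype=float)
        if (W < 0).any():
            raise ValueError("weights must be nonnegative")
        if V is None:
            row_sums = W.sum(axis=1, keepdims=True)
            V = np.divide(W, row_sums, out=np.zeros_like(W), where=row_sums > 0).T
        else:
            V = np.asarray(V, dtype=float)
            if V.shape != W.T.shape:
                raise ValueError("V must have the transposed shape of W")
        n_units, n_inputs = W.shape
        shape = (lambda n: (n,) if batch is None else (n, batch))
        return cls(W=W, V=V, y=np.zeros(shape(n_units)), e=np.zeros(shape(n_inputs)), r=np.zeros(shape(n_inputs)))

    def reset(self, batch: int | None = None) -> "LayerState":
        return LayerState.from_weights(self.W, V=self.V, batch=batch)


@dataclass(frozen=True)
class Vocabulary:
    """Five-letter lexicon plus the per-character frequencies used for weighting.

    ``letter_frequencies`` maps every character of the 36-character alphabet
    to a relative frequency; frequencies must sum to one.
    """

    words: tuple
    letter_frequencies: dict

    def __post_init__(self):
        words = tuple(w.upper() for w in self.words)
        if any(len(w) != STRING_LENGTH for w in words):
            bad = next(w for w in words if len(w) != STRING_LENGTH)
            raise ValueError(f"all words must have length {STRING_LENGTH}; got {bad!r}")
        if len(set(words)) != len(words):
            raise ValueError("vocabulary contains duplicate words")
        total = sum(self.letter_frequencies.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"letter frequencies must sum to 1, got {total}")
        object.__setattr__(self, "words", words)

    def __len__(self):
        return len(self.words)

    @classmethod
    def from_text(cls, path, letter_frequencies=None) -> "Vocabulary":
        """Read a lexicon from a plain-text file, one upper-case word per line.

        Only five-letter words over the 36-character alphabet are kept, so a
        raw corpus word list can be passed directly.  If no frequency table is
        given, frequencies are estimated from the word list itself.
        """
        glyphs = default_glyph_table()
        words, seen = [], set()
        with open(path) as fh:
            for line in fh:
                w = line.split()[0].upper() if line.split() else ""
                if len(w) == STRING_LENGTH and all(c in glyphs._index for c in w) and w not in seen:
                    words.append(w)
                    seen.add(w)
        if letter_frequencies is None:
            counts = {c: 0 for c in glyphs.chars}
            for w in words:
                for c in w:
                    counts[c] += 1
            total = sum(counts.values())
            letter_frequencies = {c: n / total for c, n in counts.items()}
        return cls(tuple(words), letter_frequencies)


def default_lexicon() -> Vocabulary:
    """The packaged English five-letter lexicon.

    Letter frequencies are estimated from the word list itself.  This is a
    stand-in lexicon with realistic orthographic structure (shared letter
    chunks, realistic letter frequencies, sparse neighbourhoods for rare
    letters), which matters for word-level dynamics: a lexicon of uniform
    random strings has dense neighbourhoods through whatever letters the
    random frequencies favour, and top-down support from partially matching
    words can then capture the middle-letter competition in ways no natural
    orthography produces.
    """
    from importlib import resources

    raw = resources.files("lexnet.assets").joinpath("english_five_letter_words.txt").read_text()
    words = tuple(sorted({w.strip().upper() for w in raw.split() if w.strip()}))
    counts = {c: 0 for c in default_glyph_table().chars}
    for w in words:
        for c in w:
            counts[c] += 1
    total = sum(counts.values())
    return Vocabulary(words, {c: n / total for c, n in counts.items()})


VOWELS = frozenset("AEIOU")


def _letter_distribution(letter_frequencies) -> tuple:
    letters = sorted(c for c, f in letter_frequencies.items()
                     if f > 0 and not c.isdigit())
    p = np.array([letter_frequencies[c] for c in letters], dtype=float)
    if not letters:
        raise ValueError("no letters with positive frequency")
    return letters, p / p.sum()


def make_nonwords(vocab: Vocabulary, rng: np.random.Generator, n: int,
                  middle: str | None = None) -> list:
    """Generate ``n`` distinct unpronounceable nonwords.

    Letters are sampled independently from the vocabulary's letter
    frequencies; candidates are rejected when any two adjacent letters are
    identical, when the string contains two or more vowels (so the strings
    are orthographically illegal rather than word-like), or when the string
    is a vocabulary member or a duplicate.  If ``middle`` is given, the
    middle slot is fixed to that letter (it counts towards the vowel limit).
    """
    letters, p = _letter_distribution(vocab.letter_frequencies)
    members = set(vocab.words)
    out: list = []
    seen: set = set()
    for _ in range(2000 * n):
        if len(out) == n:
            break
        draw = [letters[i] for i in rng.choice(len(letters), size=STRING_LENGTH, p=p)]
        if middle is not None:
            draw[MIDDLE_SLOT] = middle
        cand = "".join(draw)
        if any(a == b for a, b in zip(cand, cand[1:])):
            continue
        if sum(c in VOWELS for c in cand) >= 2:
            continue
        if cand in members or cand in seen:
            continue
        seen.add(cand)
        out.append(cand)
    if len(out) < n:
        raise RuntimeError("could not generate enough distinct nonwords")
    return out


def sample_vocabulary(rng: np.random.Generator, n_words: int = 1000,
                      positional_frequencies=None,
                      min_middle: int = 48) -> Vocabulary:
    """Sample a stand-in vocabulary of unique five-letter strings.

    Letters are drawn per slot from ``positional_frequencies`` (a sequence of
    five letter->frequency maps; defaults to frequencies estimated per slot
    from the packaged English lexicon).  At least ``min_middle`` words are
    guaranteed to carry middle letter U and as many middle letter N, so the
    word condition of a simulated run can always be filled.
    """
    if positional_frequencies is None:
        base = default_lexicon()
        positional_frequencies = []
        for slot in range(STRING_LENGTH):
            counts: dict = {}
            for w in base.words:
                counts[w[slot]] = counts.get(w[slot], 0) + 1
            total = sum(counts.values())
            positional_frequencies.append({c: k / total for c, k in counts.items()})
    if len(positional_frequencies) != STRING_LENGTH:
        raise ValueError("need one frequency table per slot")
    dists = [_letter_distribution(f) for f in positional_frequencies]
    if 2 * min_middle > n_words:
        raise ValueError("min_middle quotas exceed the vocabulary size")

    words: list = []
    seen: set = set()

    def draw(middle=None):
        s = [ls[int(rng.choice(len(ls), p=p))] for ls, p in dists]
        if middle is not None:
            s[MIDDLE_SLOT] = middle
        return "".join(s)

    for middle, quota in (("U", min_middle), ("N", min_middle), (None, 0)):
        target = len(words) + quota if middle else n_words
        tries = 0
        while len(words) < target:
            tries += 1
            if tries > 10000 * max(quota, n_words):
                raise RuntimeError("could not sample enough distinct words")
            w = draw(middle)
            if w not in seen:
                seen.add(w)
                words.append(w)
    counts = {c: 0 for c in default_glyph_table().chars}
    for w in words:
        for c in w:
            counts[c] += 1
    total = sum(counts.values())
    return Vocabulary(tuple(sorted(words)), {c: k / total for c, k in counts.items()})


@dataclass(frozen=True)
class StimulusSet:
    """Stimuli of one simulated run: (string, condition, is_target) triples."""

    items: tuple
    seed: int

    def __post_init__(self):
        for s, cond, _ in self.items:
            if len(s) != STRING_LENGTH:
                raise ValueError(f"stimulus {s!r} does not have length {STRING_LENGTH}")
            if cond not in ("word", "nonword"):
                raise ValueError(f"unknown condition {cond!r}")

    def strings(self, condition=None):
        return [s for s, c, _ in self.items if condition is None or c == condition]


# ---------------------------------------------------------------------------
# elementary operations


def corrupt_with_noise(x: np.ndarray, cfg: NetworkConfig, rng: np.random.Generator) -> np.ndarray:
    """Add Gaussian feature noise and zero any entries that turn negative."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("input features must be nonnegative")
    if cfg.noise_sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    noisy = x + rng.normal(cfg.noise_mu, cfg.noise_sigma, size=x.shape)
    return np.maximum(noisy, 0.0)


def build_letter_level(glyphs: GlyphTable | None = None, cfg: NetworkConfig = TOP_DOWN) -> LayerState:
    """Construct the letter-stage weights.

    ``W`` is 180 x 250.  The first 70 columns are feedforward: the unit for
    character ``c`` at slot ``s`` carries ``phi(c)`` in its own 14-feature
    slot and zeros elsewhere; each *row* is then rescaled to sum to one, so a
    unit's input is the mean evidence over its own strokes and a character
    with few strokes is never out-scored on its exact glyph by a character
    whose glyph is a strict superset.  The last 180 columns route the
    word-level feedback and are an identity matrix scaled by
    ``cfg.feedback_gain``; with a vanishing gain the reconstruction of the
    feedback channel falls below ``epsilon2``, the clamp caps the feedback
    error term, and the level is effectively purely bottom-up.

    ``V`` is built from the *gain-free* weights ``[ff | I]`` transposed, so
    the feedback gain controls top-down drive without rescaling the
    reconstruction: a unit reconstructs its strokes (normalised glyph) and
    its own feedback channel at unit weight regardless of the gain.
    """
    glyphs = glyphs or default_glyph_table()
    ff = np.zeros((N_LETTER_UNITS, N_FEATURES))
    for slot in range(STRING_LENGTH):
        rows = slice(slot * N_CHARS, (slot + 1) * N_CHARS)
        cols = slice(slot * 14, (slot + 1) * 14)
        ff[rows, cols] = glyphs.codes
    ff = ff / ff.sum(axis=1, keepdims=True)
    W = np.hstack([ff, cfg.feedback_gain * np.eye(N_LETTER_UNITS)])
    V = np.hstack([ff, np.eye(N_LETTER_UNITS)]).T
    return LayerState.from_weights(W, V=V)


#: Feedforward weight of each single-character unit at the word stage.  A
#: word unit's row sums to one spread over its five letters, so a word
#: matching all five letters of the input scores 1 while a word matching four
#: of five scores at most 4/5; single-character units sit between those
#: bounds.  They therefore win the competition for any letter that no fully
#: matching word accounts for (so lexical neighbours sharing four letters
#: cannot capture a slot), yet lose to an exact lexical match (so word
#: context still enhances its letters).
CHAR_UNIT_WEIGHT = 0.88


def build_word_level(vocab: Vocabulary, glyphs: GlyphTable | None = None,
                     char_unit_weight: float = CHAR_UNIT_WEIGHT) -> LayerState:
    """Construct the word-stage weights.

    One row per vocabulary word followed by 180 single-character rows; 180
    columns (5 x 36 letter-position units).  The row for word ``w`` is
    nonzero exactly at the five (slot, letter) units of ``w`` and is rescaled
    to sum to one (a uniform 1/5 per letter: scaling a whole row by the
    word's corpus frequency is cancelled by this normalisation).  The row for
    the single-character unit of (slot, letter) ``u`` carries
    ``char_unit_weight`` at column ``u`` alone, letting characters compete
    with words for every slot.  ``V`` is the transposed ``W`` with per-unit
    columns rescaled to sum to one, so a word unit reconstructs its five
    letters at 1/5 each and a character unit reconstructs its letter at unit
    weight.

    The order of word units matches ``vocab.words``; recognition is read out
    as ``argmax`` over the first ``len(vocab)`` rows of ``y``.
    """
    glyphs = glyphs or default_glyph_table()
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    if not 0 < char_unit_weight < 1:
        raise ValueError("char_unit_weight must lie strictly between 0 and 1")
    W = np.zeros((len(vocab) + N_LETTER_UNITS, N_LETTER_UNITS))
    for i, w in enumerate(vocab.words):
        for slot, c in enumerate(w):
            W[i, slot * N_CHARS + glyphs.index(c)] = 1.0
    W[:len(vocab)] /= W[:len(vocab)].sum(axis=1, keepdims=True)
    W[len(vocab):] = char_unit_weight * np.eye(N_LETTER_UNITS)
    return LayerState.from_weights(W)


def dim_step(layer: LayerState, x: np.ndarray, cfg: NetworkConfig) -> LayerState:
    """One divisive-input-modulation update of a stage, given its input ``x``.

    The error uses the reconstruction from the *previous* step held in
    ``layer.r``; the returned state carries the fresh ``y``, ``e`` and ``r``.
    Accepts a vector input or an (inputs x batch) matrix.
    """
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any() or np.isnan(layer.y).any():
        raise ValueError("NaN in network input or state")
    if (x < 0).any() or (np.asarray(layer.y) < 0).any():
        raise ValueError("network inputs and activations must be nonnegative")
    e = x / np.maximum(layer.r, cfg.epsilon2)
    y = np.maximum(layer.y, cfg.epsilon1) * (layer.W @ e)
    r = layer.V @ y
    return replace(layer, y=y, e=e, r=r)


def relative_evidence(y: np.ndarray, letter: str | int, slot: int = MIDDLE_SLOT,
                      glyphs: GlyphTable | None = None):
    """Relative evidence ``q`` for ``letter`` at ``slot``.

    ``q`` is the activation of the correct letter unit divided by the summed
    activation of the 36 letter units at the slot; an all-zero slot yields
    NaN.  ``y`` may be a vector of 180 activations or a (180 x batch) matrix
    (then ``letter`` may be a sequence, one per column).
    """
    y = np.asarray(y, dtype=float)
    glyphs = glyphs or default_glyph_table()
    block = y[slot * N_CHARS:(slot + 1) * N_CHARS]
    total = block.sum(axis=0)
    if y.ndim == 1:
        ci = letter if isinstance(letter, (int, np.integer)) else glyphs.index(letter)
        return block[ci] / total if total > 0 else float("nan")
    letters = [letter] * y.shape[1] if isinstance(letter, (str, int, np.integer)) else list(letter)
    idx = [l if isinstance(l, (int, np.integer)) else glyphs.index(l) for l in letters]
    with np.errstate(invalid="ignore", divide="ignore"):
        q = block[idx, np.arange(y.shape[1])] / total
    return np.where(total > 0, q, np.nan)


def luce_response(y_slot: np.ndarray, beta: float) -> np.ndarray:
    """Luce's choice rule: ``p_i = exp(beta*y_i) / sum_j exp(beta*y_j)``.

    Computed with max-subtraction so the result is invariant to adding a
    constant to all activations and never overflows.
    """
    y = np.asarray(y_slot, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("activations must be finite")
    z = beta * y
    z = z - z.max(axis=0, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# hierarchy and experiment


def run_hierarchy(x: np.ndarray, letter: LayerState, word: LayerState, cfg: NetworkConfig) -> dict:
    """Run the two-stage hierarchy on noisy feature input for ``cfg.n_iterations``.

    Per iteration the letter stage is updated first, on the concatenation of
    the 70 visual features and the word stage's reconstruction of the letter
    units from the previous iteration (zero at iteration one, so the first
    sweep is purely feedforward); the word stage is then updated on the fresh
    letter predictions.  Both stages start from zero activations.

    ``x`` is a 70-vector or (70 x batch) matrix.  Returns the final states and
    the letter-stage predictions.
    """
    x = np.asarray(x, dtype=float)
    batch = None if x.ndim == 1 else x.shape[1]
    if x.shape[0] != N_FEATURES:
        raise ValueError(f"input must have {N_FEATURES} features, got {x.shape[0]}")
    if word.W.shape[1] != N_LETTER_UNITS or letter.W.shape[0] != N_LETTER_UNITS:
        raise ValueError("letter and word stages are dimensionally incompatible")
    letter = letter.reset(batch)
    word = word.reset(batch)
    for _ in range(cfg.n_iterations):
        x_full = np.concatenate([x, word.r], axis=0)
        letter = dim_step(letter, x_full, cfg)
        word = dim_step(word, letter.y, cfg)
    return {"letter": letter, "word": word, "y_letter": letter.y}


def make_stimulus_run(vocab: Vocabulary, nonword_pool, word_targets, nonword_targets,
                      rng: np.random.Generator, n_per_condition: int = 48,
                      target_fraction: float = 0.12) -> StimulusSet:
    """Assemble one run: words and nonwords, middle letters balanced (U/N),
    with ``target_fraction`` of each condition replaced by learned targets.

    ``word_targets`` and ``nonword_targets`` each hold one U-middle and one
    N-middle string; nonword targets are expected to be vocabulary members
    (they were learned), which contaminates the nonword condition exactly as
    in the experimental design.
    """
    half = n_per_condition // 2
    words_u = [w for w in vocab.words if w[MIDDLE_SLOT] == "U" and w not in word_targets]
    words_n = [w for w in vocab.words if w[MIDDLE_SLOT] == "N" and w not in word_targets]
    if len(words_u) < half or len(words_n) < half:
        raise ValueError("vocabulary lacks enough U-middle or N-middle words for a run")
    nw_u = [w for w in nonword_pool if w[MIDDLE_SLOT] == "U"]
    nw_n = [w for w in nonword_pool if w[MIDDLE_SLOT] == "N"]
    if len(nw_u) < half or len(nw_n) < half:
        raise ValueError("nonword pool lacks enough U-middle or N-middle items")
    seed = int(rng.integers(2 ** 31))

    def pick(pool, k):
        return [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]

    n_targets = round(target_fraction * n_per_condition)
    items = []
    for cond, (pool_u, pool_n, targets) in (
        ("word", (words_u, words_n, word_targets)),
        ("nonword", (nw_u, nw_n, nonword_targets)),
    ):
        sel = pick(pool_u, half) + pick(pool_n, half)
        t_u = next(t for t in targets if t[MIDDLE_SLOT] == "U")
        t_n = next(t for t in targets if t[MIDDLE_SLOT] == "N")
        for i in range(n_targets):
            # replace alternately in the U-middle and N-middle halves
            sel[i // 2 if i % 2 == 0 else half + i // 2] = t_u if i % 2 == 0 else t_n
        items += [(s, cond, s in targets) for s in sel]
    return StimulusSet(tuple(items), seed)


def simulate_experiment(vocab: Vocabulary, stimulus_runs, cfg_top_down: NetworkConfig = TOP_DOWN,
                        cfg_feedforward: NetworkConfig = FEEDFORWARD,
                        glyphs: GlyphTable | None = None, rng: np.random.Generator | None = None):
    """Present every run to the top-down and feedforward models and test the
    word-superiority dissociation.

    Both configurations must be identical except for the feedback gain, and
    both models see the identical noisy inputs per run (the same noise
    realisation), so the interaction test isolates the effect of feedback.

    Returns ``(results, stats)``: ``results`` is a long-format table with one
    row per run x model x condition holding the mean relative evidence of the
    middle letter and the mean Luce probability of the correct response;
    ``stats`` holds the per-model paired t-tests across runs and the
    two-sample interaction t-test on per-run word-nonword differences.
    """
    import pandas as pd

    if replace(cfg_top_down, feedback_gain=1.0) != replace(cfg_feedforward, feedback_gain=1.0):
        raise ValueError("the two configurations may differ only in feedback_gain")
    n_runs = len(stimulus_runs)
    if n_runs < 2:
        raise ValueError("at least two runs are required for the statistics")
    glyphs = glyphs or default_glyph_table()
    rng = rng or np.random.default_rng(0)
    word_layer = build_word_level(vocab, glyphs)
    layers = {
        "top_down": build_letter_level(glyphs, cfg_top_down),
        "feedforward": build_letter_level(glyphs, cfg_feedforward),
    }
    cfgs = {"top_down": cfg_top_down, "feedforward": cfg_feedforward}

    rows, detail = [], []
    for run_idx, stim in enumerate(stimulus_runs):
        strings = [s for s, _, _ in stim.items]
        conds = np.array([c for _, c, _ in stim.items])
        mid = [s[MIDDLE_SLOT] for s in strings]
        X = np.stack([glyphs.encode_string(s) for s in strings], axis=1)
        noise_rng = np.random.default_rng(stim.seed)
        X_noisy = corrupt_with_noise(X, cfg_top_down, noise_rng)
        for model, layer in layers.items():
            out = run_hierarchy(X_noisy, layer, word_layer, cfgs[model])
            q = relative_evidence(out["y_letter"], mid, glyphs=glyphs)
            block = out["y_letter"][MIDDLE_SLOT * N_CHARS:(MIDDLE_SLOT + 1) * N_CHARS]
            p = luce_response(block, cfgs[model].beta)
            p_correct = p[[glyphs.index(m) for m in mid], np.arange(len(mid))]
            for cond in ("word", "nonword"):
                m = conds == cond
                rows.append({"run": run_idx, "model": model, "condition": cond,
                             "mean_q": float(np.nanmean(q[m])),
                             "mean_luce_correct": float(p_correct[m].mean())})
            for i, s in enumerate(strings):
                detail.append({"run": run_idx, "model": model, "stimulus": s,
                               "condition": conds[i], "middle": mid[i],
                               "q": float(q[i]), "luce_correct": float(p_correct[i])})
    results = pd.DataFrame(rows)
    detail = pd.DataFrame(detail)

    stats_out, diffs = {}, {}
    for model in layers:
        sub = results[results.model == model].pivot(index="run", columns="condition", values="mean_q")
        t, p = stats.ttest_rel(sub["word"], sub["nonword"])
        diffs[model] = (sub["word"] - sub["nonword"]).to_numpy()
        stats_out[model] = {"t": float(t), "p": float(p), "df": n_runs - 1,
                            "mean_diff": float(diffs[model].mean())}
    t, p = stats.ttest_ind(diffs["top_down"], diffs["feedforward"])
    stats_out["interaction"] = {"t": float(t), "p": float(p), "df": 2 * n_runs - 2}
    return results, {"stats": stats_out, "detail": detail}
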