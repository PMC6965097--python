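"""Multi-voxel pattern analysis of letter identity in visual cortex.

Trial-wise decoding of the middle letter (U vs N) from voxel patterns with a
logistic-regression classifier trained on a functional localiser, split-half
pattern-correlation information scores, classifier-evidence timecourses used
as the seed of the coupling analysis, a searchlight wrapper, and a univariate
amplitude control analysis.

Preprocessing follows the study pipeline: per-run Savitzky-Golay low-pass
smoothing (third order, window 21 TRs), per-run z-scoring per voxel, a 3-TR
label shift to compensate haemodynamic lag, and averaging of the 10 TRs of
each 14-s trial (TR = 1.4 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.linear_model import LogisticRegression

TR_SECONDS = 1.4
TRS_PER_TRIAL = 10
SAVGOL_ORDER = 3
SAVGOL_WINDOW = 21
HRF_SHIFT_TRS = 3
DEFAULT_K = 200
DEFAULT_SPLITS = 12
LETTERS = ("U", "N")
CONDITIONS = ("word", "nonword")
CELLS = tuple(f"{l}-{c}" for l in LETTERS for c in CONDITIONS)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class RoiTimecourse:
    """TR x voxel signal with per-TR run/trial/condition labels.

    ``condition_labels`` take values ``{U-word, U-nonword, N-word,
    N-nonword, null}``; every non-null trial spans ``TRS_PER_TRIAL``
    consecutive TRs.  ``trial_labels`` holds an integer trial id, or -1 for
    null TRs.
    """

    values: np.ndarray
    run_labels: np.ndarray
    trial_labels: np.ndarray
    condition_labels: np.ndarray
    tr_seconds: float = TR_SECONDS

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        run = np.asarray(self.run_labels)
        trial = np.asarray(self.trial_labels)
        cond = np.asarray(self.condition_labels)
        if values.ndim != 2:
            raise ValueError("values must be a TR x voxel matrix")
        n = values.shape[0]
        if not (len(run) == len(trial) == len(cond) == n):
            raise ValueError("label arrays must match the TR axis length")
        valid = set(CELLS) | {"null"}
        bad = set(np.unique(cond)) - valid
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        for t in np.unique(trial[trial >= 0]):
            idx = np.flatnonzero(trial == t)
            if len(idx) != TRS_PER_TRIAL or (np.diff(idx) != 1).any():
                raise ValueError(
                    f"trial {t} must span exactly {TRS_PER_TRIAL} consecutive TRs")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "run_labels", run)
        object.__setattr__(self, "trial_labels", trial)
        object.__setattr__(self, "condition_labels", cond)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path):
        df = pd.DataFrame(self.values, columns=[f"v{i}" for i in range(self.n_voxels)])
        df.insert(0, "condition", self.condition_labels)
        df.insert(0, "trial", self.trial_labels)
        df.insert(0, "run", self.run_labels)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RoiTimecourse":
        # keep the literal label "null" (pandas would parse it as NaN)
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
        vox = [c for c in df.columns if c not in ("run", "trial", "condition")]
        return cls(df[vox].to_numpy(float), df["run"].to_numpy(),
                   df["trial"].to_numpy(int), df["condition"].to_numpy(str))


@dataclass(frozen=True)
class TrialPatternSet:
    """Trial x voxel patterns with per-trial letter, condition and run labels."""

    patterns: np.ndarray
    letter: np.ndarray
    condition: np.ndarray
    run: np.ndarray

    def __post_init__(self):
        patterns = np.asarray(self.patterns, dtype=float)
        letter = np.asarray(self.letter)
        condition = np.asarray(self.condition)
        run = np.asarray(self.run)
        if patterns.ndim != 2:
            raise ValueError("patterns must be a trial x voxel matrix")
        n = patterns.shape[0]
        if not (len(letter) == len(condition) == len(run) == n):
            raise ValueError("label arrays must match the trial axis length")
        if not set(np.unique(letter)) <= set(LETTERS):
            raise ValueError(f"letters must be one of {LETTERS}")
        if not set(np.unique(condition)) <= set(CONDITIONS):
            raise ValueError(f"conditions must be one of {CONDITIONS}")
        object.__setattr__(self, "patterns", patterns)
        object.__setattr__(self, "letter", letter)
        object.__setattr__(self, "condition", condition)
        object.__setattr__(self, "run", run)

    def __len__(self):
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def subset_voxels(self, idx) -> "TrialPatternSet":
        return TrialPatternSet(self.patterns[:, idx], self.letter, self.condition, self.run)

    def to_tsv(self, path):
        df = pd.DataFrame(self.patterns, columns=[f"v{i}" for i in range(self.n_voxels)])
        df.insert(0, "letter", self.letter)
        df.insert(0, "condition", self.condition)
        df.insert(0, "run", self.run)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrialPatternSet":
        df = pd.read_csv(path, sep="\t")
        vox = [c for c in df.columns if c not in ("run", "condition", "letter")]
        return cls(df[vox].to_numpy(float), df["letter"].to_numpy(str),
                   df["condition"].to_numpy(str), df["run"].to_numpy())


@dataclass(frozen=True)
class LetterClassifier:
    """Trained logistic-regression letter decoder (U coded 1, N coded 0)."""

    weights: np.ndarray
    intercept: float

    def scores(self, patterns: np.ndarray) -> np.ndarray:
        patterns = np.asarray(patterns, dtype=float)
        if patterns.shape[-1] != len(self.weights):
            raise ValueError(
                f"voxel dimension mismatch: classifier has {len(self.weights)} "
                f"voxels, patterns have {patterns.shape[-1]}")
        return patterns @ self.weights + self.intercept

    def prob_u(self, patterns: np.ndarray) -> np.ndarray:
        """Probability of letter U (the class coded 1) per pattern."""
        return 1.0 / (1.0 + np.exp(-self.scores(patterns)))

    def predict(self, patterns: np.ndarray) -> np.ndarray:
        return np.where(self.prob_u(patterns) > 0.5, "U", "N")


@dataclass(frozen=True)
class PatternInfoScore:
    """Within-letter minus between-letter split-half pattern correlation."""

    rho_within: float
    rho_between: float
    condition: str

    def __post_init__(self):
        for name in ("rho_within", "rho_between"):
            v = getattr(self, name)
            if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")

    @property
    def score(self) -> float:
        return self.rho_within - self.rho_between


@dataclass(frozen=True)
class EvidenceSeries:
    """Per-TR classifier evidence for the presented letter.

    ``evidence[t]`` is the probability the decoder assigns to the letter
    actually shown at TR ``t`` (NaN at null TRs); ``condition[t]`` is
    ``word``/``nonword``/``null``.
    """

    evidence: np.ndarray
    condition: np.ndarray
    run: np.ndarray

    def __post_init__(self):
        ev = np.asarray(self.evidence, dtype=float)
        cond = np.asarray(self.condition)
        run = np.asarray(self.run)
        if not (len(ev) == len(cond) == len(run)):
            raise ValueError("evidence, condition and run must have equal length")
        live = cond != "null"
        if np.isnan(ev[live]).any():
            raise ValueError("evidence must be defined at all non-null TRs")
        if ((ev[live] <= 0) | (ev[live] >= 1)).any():
            raise ValueError("evidence values must lie strictly in (0, 1)")
        object.__setattr__(self, "evidence", ev)
        object.__setattr__(self, "condition", cond)
        object.__setattr__(self, "run", run)

    def __len__(self):
        return len(self.evidence)

    def to_tsv(self, path):
        pd.DataFrame({"tr": np.arange(len(self)), "run": self.run,
                      "condition": self.condition, "evidence": self.evidence}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EvidenceSeries":
        # keep the literal label "null" (pandas would parse it as NaN)
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
        return cls(df["evidence"].to_numpy(float), df["condition"].to_numpy(str),
                   df["run"].to_numpy())


# ---------------------------------------------------------------------------
# preprocessing


def _preprocess_values(tc: RoiTimecourse) -> np.ndarray:
    """Savitzky-Golay smoothing + z-scoring per voxel per run."""
    out = np.empty_like(tc.values)
    for r in np.unique(tc.run_labels):
        rows = np.flatnonzero(tc.run_labels == r)
        if (np.diff(rows) != 1).any():
            raise ValueError(f"run {r} is not contiguous")
        if len(rows) < SAVGOL_WINDOW:
            raise ValueError(
                f"run {r} has {len(rows)} TRs, fewer than the smoothing window "
                f"({SAVGOL_WINDOW})")
        sm = signal.savgol_filter(tc.values[rows], SAVGOL_WINDOW, SAVGOL_ORDER, axis=0)
        mu = sm.mean(axis=0)
        sd = sm.std(axis=0)
        # flag dead voxels on the raw signal: smoothing a constant leaves
        # O(1e-14) convolution jitter that z-scoring would amplify
        dead = tc.values[rows].std(axis=0) == 0
        if dead.any():
            warnings.warn(
                f"run {r}: {int(dead.sum())} zero-variance voxel(s); z-scores set to 0")
            sd = np.where(dead, 1.0, sd)
        z = (sm - mu) / sd
        z[:, dead] = 0.0
        out[rows] = z
    return out


def _shifted_labels(tc: RoiTimecourse):
    """Trial/condition labels shifted ``HRF_SHIFT_TRS`` TRs later, per run."""
    trial = np.full_like(tc.trial_labels, -1)
    cond = np.full(tc.condition_labels.shape, "null", dtype=object)
    for r in np.unique(tc.run_labels):
        rows = np.flatnonzero(tc.run_labels == r)
        src = rows[:-HRF_SHIFT_TRS]
        dst = rows[HRF_SHIFT_TRS:]
        trial[dst] = tc.trial_labels[src]
        cond[dst] = tc.condition_labels[src]
    return trial, np.asarray(cond, dtype=str)


def preprocess_timecourses(tc: RoiTimecourse) -> TrialPatternSet:
    """Smooth, z-score per run, shift labels 3 TRs, average TRs per trial.

    Null trials are dropped.  The TRs of a trial that fall past the end of
    its run after the shift are lost; the trial average uses the remaining
    TRs.
    """
    z = _preprocess_values(tc)
    trial, cond = _shifted_labels(tc)
    ids = np.unique(trial[trial >= 0])
    patterns, letters, conditions, runs = [], [], [], []
    for t in ids:
        rows = np.flatnonzero(trial == t)
        cell = cond[rows[0]]
        if cell == "null":
            continue
        letter, condition = cell.split("-")
        patterns.append(z[rows].mean(axis=0))
        letters.append(letter)
        conditions.append(condition)
        runs.append(tc.run_labels[rows[0]])
    return TrialPatternSet(np.array(patterns), np.array(letters),
                           np.array(conditions), np.array(runs))


def preprocess_per_tr(tc: RoiTimecourse):
    """Per-TR preprocessed patterns with shifted labels, for evidence_series.

    Returns ``(patterns, letter_per_tr, condition_per_tr)`` where letters and
    conditions are ``None``-free strings with ``null`` marking rest TRs.  The
    treatment of the data is identical to the trial-level path (smoothing,
    per-run z-scoring, 3-TR shift); only the within-trial averaging is
    skipped.
    """
    z = _preprocess_values(tc)
    _, cond = _shifted_labels(tc)
    letters = np.array([c.split("-")[0] if c != "null" else "null" for c in cond])
    conditions = np.array([c.split("-")[1] if c != "null" else "null" for c in cond])
    return z, letters, conditions


# ---------------------------------------------------------------------------
# decoding


def select_voxels(zstats, mode: str = "topk", k: int = DEFAULT_K,
                  localiser_zstats=None) -> np.ndarray:
    """Voxel selection by localiser statistics.

    ``topk`` returns the indices of the ``k`` largest values (ties broken by
    lowest index).  ``peripheral`` returns voxels in the top 50% of
    ``zstats`` (main-experiment statistics) and simultaneously in the bottom
    50% of ``localiser_zstats``.
    """
    zstats = np.asarray(zstats, dtype=float)
    if not np.isfinite(zstats).all():
        raise ValueError("statistics must be finite")
    if mode == "topk":
        if k <= 0:
            raise ValueError("k must be positive")
        if k > len(zstats):
            raise ValueError(f"k = {k} exceeds the voxel count {len(zstats)}")
        # stable selection: sort by (-value, index)
        order = np.lexsort((np.arange(len(zstats)), -zstats))
        return np.sort(order[:k])
    if mode == "peripheral":
        if localiser_zstats is None:
            raise ValueError("peripheral mode needs localiser_zstats")
        loc = np.asarray(localiser_zstats, dtype=float)
        if not np.isfinite(loc).all():
            raise ValueError("statistics must be finite")
        main_top = zstats >= np.median(zstats)
        loc_bottom = loc <= np.median(loc)
        return np.flatnonzero(main_top & loc_bottom)
    raise ValueError(f"unknown mode {mode!r}")


def voxel_selectivity(tps: TrialPatternSet) -> np.ndarray:
    """Per-voxel letter selectivity: |two-sample t| between U and N trials."""
    u = tps.patterns[tps.letter == "U"]
    n = tps.patterns[tps.letter == "N"]
    if len(u) < 2 or len(n) < 2:
        raise ValueError("need at least two trials per letter")
    from scipy import stats as _stats

    t, _ = _stats.ttest_ind(u, n, axis=0)
    return np.abs(np.nan_to_num(t))


def train_letter_classifier(localiser: TrialPatternSet) -> LetterClassifier:
    """L2-regularised logistic regression on localiser patterns only.

    Inverse regularisation strength 1.0, fitted intercept, tolerance 1e-4
    (the decoder library's defaults).
    """
    labels = np.asarray(localiser.letter)
    if len(np.unique(labels)) < 2:
        raise ValueError("localiser must contain both letter classes")
    y = (labels == "U").astype(int)
    clf = LogisticRegression()
    clf.fit(localiser.patterns, y)
    return LetterClassifier(weights=clf.coef_.ravel().copy(),
                            intercept=float(clf.intercept_[0]))


def decode_by_condition(clf: LetterClassifier, main: TrialPatternSet) -> dict:
    """Trial-wise decoding accuracy per condition and overall."""
    pred = clf.predict(main.patterns)
    correct = pred == main.letter
    out = {}
    for cond in CONDITIONS:
        m = main.condition == cond
        if not m.any():
            raise ValueError(f"no trials in condition {cond!r}")
        out[cond] = float(correct[m].mean())
    out["overall"] = float(correct.mean())
    return out


def evidence_series(clf: LetterClassifier, patterns: np.ndarray,
                    letter_per_tr, condition_per_tr, run_per_tr) -> EvidenceSeries:
    """Per-TR probability assigned to the letter actually presented.

    For TRs with letter U the evidence is the decoder's probability of U;
    for N it is the complement.  Null TRs get NaN.
    """
    letter = np.asarray(letter_per_tr)
    cond = np.asarray(condition_per_tr)
    live = cond != "null"
    if (~np.isin(letter[live], LETTERS)).any():
        raise ValueError("non-null TRs must carry a letter label U or N")
    p_u = clf.prob_u(patterns)
    ev = np.where(letter == "U", p_u, 1.0 - p_u)
    ev = np.where(live, ev, np.nan)
    return EvidenceSeries(ev, cond, np.asarray(run_per_tr))


# ---------------------------------------------------------------------------
# pattern-correlation information


def pattern_correlation_info(main: TrialPatternSet, n_repeats: int = DEFAULT_SPLITS,
                             rng: np.random.Generator | None = None) -> dict:
    """Split-half pattern correlation scores per condition.

    Per repeat, trials are halved within each letter x condition cell; each
    half's patterns are averaged per cell.  For each condition,
    ``rho_within`` averages the two same-letter cross-split correlations and
    ``rho_between`` the two different-letter cross-split pairings.  Scores
    are averaged over ``n_repeats`` repeats.
    """
    rng = rng or np.random.default_rng(0)
    cells = {}
    for l in LETTERS:
        for c in CONDITIONS:
            idx = np.flatnonzero((main.letter == l) & (main.condition == c))
            if len(idx) < 2:
                raise ValueError(f"condition cell {l}-{c} has fewer than 2 trials")
            cells[(l, c)] = idx

    acc = {c: {"within": [], "between": []} for c in CONDITIONS}
    for _ in range(n_repeats):
        half1, half2 = {}, {}
        for key, idx in cells.items():
            perm = rng.permutation(idx)
            h = len(perm) // 2
            half1[key] = main.patterns[perm[:h]].mean(axis=0)
            half2[key] = main.patterns[perm[h:2 * h]].mean(axis=0)
        for c in CONDITIONS:
            within = [np.corrcoef(half1[(l, c)], half2[(l, c)])[0, 1] for l in LETTERS]
            between = [np.corrcoef(half1[("U", c)], half2[("N", c)])[0, 1],
                       np.corrcoef(half1[("N", c)], half2[("U", c)])[0, 1]]
            acc[c]["within"].append(np.mean(within))
            acc[c]["between"].append(np.mean(between))
    return {c: PatternInfoScore(rho_within=float(np.mean(acc[c]["within"])),
                                rho_between=float(np.mean(acc[c]["between"])),
                                condition=c)
            for c in CONDITIONS}


# ---------------------------------------------------------------------------
# searchlight


def sphere_members(coords_mm: np.ndarray, centre: int, radius_mm: float) -> np.ndarray:
    """Indices of voxels whose centre lies within ``radius_mm`` of ``centre``."""
    d = np.linalg.norm(coords_mm - coords_mm[centre], axis=1)
    return np.flatnonzero(d <= radius_mm)


def searchlight_map(coords_mm: np.ndarray, localiser: TrialPatternSet,
                    main: TrialPatternSet, radius_mm: float = 6.0,
                    metric: str = "decode", voxel_size_mm: float = 2.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-voxel searchlight score map.

    For every voxel, the sphere of voxels within ``radius_mm`` (Euclidean
    centre-to-centre distance, inclusive) forms the ROI; the chosen metric is
    evaluated on that ROI and written at the sphere centre.  ``decode``
    scores overall decoding accuracy (classifier trained on the localiser
    sphere); ``pattern_info`` scores the word-condition pattern information.
    """
    coords_mm = np.asarray(coords_mm, dtype=float)
    if radius_mm < voxel_size_mm:
        raise ValueError("searchlight radius must be at least the voxel size")
    if coords_mm.shape[0] != main.n_voxels or coords_mm.shape[0] != localiser.n_voxels:
        raise ValueError("coordinate table must match the voxel axis")
    rng = rng or np.random.default_rng(0)
    out = np.empty(coords_mm.shape[0])
    for v in range(coords_mm.shape[0]):
        members = sphere_members(coords_mm, v, radius_mm)
        if metric == "decode":
            clf = train_letter_classifier(localiser.subset_voxels(members))
            out[v] = decode_by_condition(clf, main.subset_voxels(members))["overall"]
        elif metric == "pattern_info":
            scores = pattern_correlation_info(main.subset_voxels(members),
                                              rng=np.random.default_rng(rng.integers(2 ** 31)))
            out[v] = scores["word"].score
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


# ---------------------------------------------------------------------------
# univariate amplitude control


def univariate_amplitude(tc: RoiTimecourse, condition_regressors: np.ndarray,
                         names, nuisance: np.ndarray | None = None) -> dict:
    """Per-condition amplitude estimates from run-wise GLM fits.

    ``condition_regressors`` is a TR x condition matrix of HRF-convolved
    boxcars with columns labelled by ``names``; ``nuisance`` holds optional
    extra columns (motion etc.).  Each run is fitted separately on the mean
    ROI timecourse (the voxel average) with an intercept; run-level betas are
    combined as an unweighted mean (fixed effects).
    """
    X_cond = np.asarray(condition_regressors, dtype=float)
    names = list(names)
    if X_cond.shape[0] != tc.values.shape[0]:
        raise ValueError("condition regressors must span the timecourse")
    if X_cond.shape[1] != len(names):
        raise ValueError("one name per condition regressor required")
    y_all = tc.values.mean(axis=1)
    betas = []
    for r in np.unique(tc.run_labels):
        rows = np.flatnonzero(tc.run_labels == r)
        X = X_cond[rows]
        if nuisance is not None:
            X = np.hstack([X, np.asarray(nuisance, dtype=float)[rows]])
        X = np.hstack([X, np.ones((len(rows), 1))])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _collinear_columns(X, names + [f"nuisance{i}" for i in
                                                 range(X.shape[1] - len(names) - 1)] + ["intercept"])
            raise ValueError(f"rank-deficient design in run {r}: {bad}")
        beta, *_ = np.linalg.lstsq(X, y_all[rows], rcond=None)
        betas.append(beta[:len(names)])
    mean_beta = np.mean(betas, axis=0)
    return {name: float(b) for name, b in zip(names, mean_beta)}


def _collinear_columns(X: np.ndarray, names) -> list:
    """Names of columns that do not increase the design rank."""
    bad, kept = [], np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.hstack([kept, X[:, j:j + 1]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(names[j])
    return bad


def roi_size_sweep(zstats, localiser: TrialPatternSet, main: TrialPatternSet,
                   ks=range(50, 1001, 10)) -> pd.DataFrame:
    """Decoding accuracy as a function of ROI size ``k`` (top-k selection)."""
    rows = []
    for k in ks:
        idx = select_voxels(zstats, "topk", k=min(k, len(np.asarray(zstats))))
        clf = train_letter_classifier(localiser.subset_voxels(idx))
        acc = decode_by_condition(clf, main.subset_voxels(idx))
        rows.append({"k": k, **acc})
    return pd.DataFrame(rows)
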