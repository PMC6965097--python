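"""Information-activation coupling: GLM of regional BOLD on classifier evidence.

The seed regressor is the per-TR classifier evidence for the presented
letter, split into a word and a nonword regressor (each zero at the other
condition's TRs).  First-order temporal derivatives of both evidence
regressors capture variability in response onset, 24 motion regressors
(six parameters, their squares, their one-TR lags and squared lags) absorb
residual motion artefacts, and null-trial TRs are omitted.  Fits use AR(1)
prewhitening, and group inference runs through the shared test-selection
gate for ROIs or a sign-flip max-cluster permutation test voxelwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .mvpa import EvidenceSeries
from .stats import gated_paired_test

N_MOTION_PARAMS = 6
N_MOTION_REGRESSORS = 24
CLUSTER_FORMING_Z = 3.1
MIN_WHITEN_TRS = 30


@dataclass(frozen=True)
class CouplingDesign:
    """GLM design with named regressor groups and the TR inclusion mask.

    ``matrix`` holds only the included (non-null) TRs; ``included`` marks
    which TRs of the original session they came from.  The default design
    has 29 columns: evidence_word, evidence_nonword, their temporal
    derivatives, 24 motion terms and an intercept; with run-wise intercepts
    the count is 28 + number of runs.
    """

    matrix: np.ndarray
    names: tuple
    included: np.ndarray

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=float)
        names = tuple(self.names)
        included = np.asarray(self.included, dtype=bool)
        if matrix.shape[1] != len(names):
            raise ValueError("one name per design column required")
        if matrix.shape[0] != included.sum():
            raise ValueError("matrix rows must match the inclusion mask")
        iw = matrix[:, names.index("evidence_word")]
        inw = matrix[:, names.index("evidence_nonword")]
        if (iw * inw != 0).any():
            raise ValueError("evidence regressors must be condition-exclusive")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "included", included)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass(frozen=True)
class CouplingResult:
    """Condition-wise coupling slopes for one target (ROI or voxel)."""

    beta_word: float
    beta_nonword: float
    ar1_rho: float

    def __post_init__(self):
        for name in ("beta_word", "beta_nonword", "ar1_rho"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not -1 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in (-1, 1)")

    @property
    def difference(self) -> float:
        return self.beta_word - self.beta_nonword


def friston_24(motion: np.ndarray) -> np.ndarray:
    """Expand 6 motion parameters to 24 regressors: p, p**2, lag-1 p, lag-1 p**2."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != N_MOTION_PARAMS:
        raise ValueError(f"motion must be TR x {N_MOTION_PARAMS}")
    lag = np.vstack([np.zeros((1, N_MOTION_PARAMS)), motion[:-1]])
    return np.hstack([motion, motion ** 2, lag, lag ** 2])


def build_coupling_design(ev: EvidenceSeries, motion: np.ndarray,
                          run_intercepts: bool = False) -> CouplingDesign:
    """Assemble the coupling design from evidence and motion series.

    Evidence is split by condition; temporal derivatives (first differences,
    zero at the first TR) are appended; motion is Volterra-expanded to 24
    columns; null TRs are dropped from every column after the temporal
    operations; an intercept (or one per run) completes the design.
    """
    motion = np.asarray(motion, dtype=float)
    if len(motion) != len(ev):
        raise ValueError("evidence and motion must share the TR axis")
    live = ev.condition != "null"
    if not live.any():
        raise ValueError("session contains no non-null TRs")
    evid = np.nan_to_num(ev.evidence, nan=0.0)
    ev_word = np.where(ev.condition == "word", evid, 0.0)
    ev_nonword = np.where(ev.condition == "nonword", evid, 0.0)
    deriv = lambda x: np.diff(x, prepend=x[:1])
    cols = [ev_word, ev_nonword, deriv(ev_word), deriv(ev_nonword)]
    names = ["evidence_word", "evidence_nonword", "deriv_word", "deriv_nonword"]
    mot = friston_24(motion)
    cols += [mot[:, j] for j in range(N_MOTION_REGRESSORS)]
    names += [f"motion{j}" for j in range(N_MOTION_REGRESSORS)]
    if run_intercepts:
        for r in np.unique(ev.run):
            cols.append((ev.run == r).astype(float))
            names.append(f"intercept_run{r}")
    else:
        cols.append(np.ones(len(ev)))
        names.append("intercept")
    matrix = np.column_stack(cols)[live]
    return CouplingDesign(matrix, tuple(names), live)


def ar1_prewhiten(Y: np.ndarray, X: np.ndarray, rho: float | None = None):
    """AR(1) prewhitening of response and design.

    ``rho`` defaults to the lag-1 autocorrelation of the OLS residuals.  Rows
    are transformed v_t -> v_t - rho * v_{t-1}; the first row is scaled by
    sqrt(1 - rho**2).  Returns ``(Y_white, X_white, rho)``.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] < MIN_WHITEN_TRS:
        raise ValueError(f"need at least {MIN_WHITEN_TRS} usable TRs")
    if rho is None:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        res = Y - X @ beta
        res = res - res.mean(axis=0)
        num = (res[1:] * res[:-1]).sum(axis=0)
        den = (res ** 2).sum(axis=0)
        rho = float(np.mean(np.divide(num, den, out=np.zeros_like(np.atleast_1d(num), dtype=float),
                                      where=np.atleast_1d(den) > 0)))
    if abs(rho) >= 1:
        raise ValueError(f"estimated AR(1) coefficient {rho} is outside (-1, 1)")

    def transform(v):
        w = v.copy().astype(float)
        w[1:] = v[1:] - rho * v[:-1]
        w[0] = np.sqrt(1 - rho ** 2) * v[0]
        return w

    return transform(Y), transform(X), rho


def fit_coupling_glm(Y: np.ndarray, design: CouplingDesign,
                     prewhiten: bool = True) -> CouplingResult:
    """OLS fit of the (whitened) coupling GLM; returns the condition slopes."""
    Y = np.asarray(Y, dtype=float)
    X = design.matrix
    if len(Y) != X.shape[0]:
        raise ValueError("response length must match the design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_collinear(X, design.names)}")
    rho = 0.0
    if prewhiten:
        Y, X, rho = ar1_prewhiten(Y, X)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return CouplingResult(
        beta_word=float(beta[design.names.index("evidence_word")]),
        beta_nonword=float(beta[design.names.index("evidence_nonword")]),
        ar1_rho=rho)


def _collinear(X: np.ndarray, names) -> list:
    bad, kept = [], np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.hstack([kept, X[:, j:j + 1]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(names[j])
    return bad


def roi_coupling_test(results) -> dict:
    """Group test on per-participant (beta_word, beta_nonword) pairs.

    Applies the normality/outlier test-selection gate to the paired slopes
    and returns the chosen statistic, p value and effect size.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("at least two participants are required")
    word = np.array([r.beta_word for r in results])
    nonword = np.array([r.beta_nonword for r in results])
    return gated_paired_test(word, nonword)


def voxelwise_coupling_map(diff_maps: np.ndarray, n_permutations: int = 1000,
                           rng: np.random.Generator | None = None,
                           cluster_forming_z: float = CLUSTER_FORMING_Z,
                           alpha: float = 0.05) -> dict:
    """Cluster-thresholded group map of coupling differences.

    ``diff_maps`` is participants x X x Y x Z (per-voxel beta_word -
    beta_nonword).  A right-tailed one-sample t-test per voxel is converted
    to z; clusters of face-connected voxels with z > ``cluster_forming_z``
    are assessed against a sign-flip max-cluster-extent permutation null.
    Returns the z map, a cluster table and the binary map of surviving
    clusters.
    """
    diff_maps = np.asarray(diff_maps, dtype=float)
    if diff_maps.ndim != 4:
        raise ValueError("diff_maps must be participants x X x Y x Z")
    n = diff_maps.shape[0]
    if n < 8:
        raise ValueError("permutation test refused with fewer than 8 participants")
    rng = rng or np.random.default_rng(0)
    structure = ndimage.generate_binary_structure(3, 1)  # face connectivity

    def zmap_of(maps):
        mean = maps.mean(axis=0)
        sd = maps.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / (sd / np.sqrt(n))
        t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
        p_right = stats.t.sf(t, df=n - 1)
        return stats.norm.isf(np.clip(p_right, 1e-300, 1 - 1e-16))

    def max_cluster(zm):
        labels, n_lab = ndimage.label(zm > cluster_forming_z, structure=structure)
        if n_lab == 0:
            return 0, labels, np.array([], dtype=int)
        sizes = np.bincount(labels.ravel())[1:]
        return int(sizes.max()), labels, sizes

    z_obs = zmap_of(diff_maps)
    _, labels, sizes = max_cluster(z_obs)

    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        flips = rng.choice((-1.0, 1.0), size=n)
        null_max[i], _, _ = max_cluster(zmap_of(diff_maps * flips[:, None, None, None]))

    clusters = []
    surviving = np.zeros(z_obs.shape, dtype=bool)
    for cid, size in enumerate(sizes, start=1):
        p = float((1 + (null_max >= size).sum()) / (1 + n_permutations))
        peak = float(z_obs[labels == cid].max())
        clusters.append({"cluster": cid, "size": int(size), "peak_z": peak, "p": p})
        if p < alpha:
            surviving |= labels == cid
    return {"z_map": z_obs, "clusters": clusters, "surviving": surviving,
            "null_max_cluster": null_max}
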