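"""Test-selection gate and effect sizes for paired condition comparisons.

Every paired comparison first checks the per-participant differences for
normality (D'Agostino-Pearson) and outliers (1.5 x IQR fences).  If both
checks pass, a paired t-test with Cohen's d is used; otherwise a Wilcoxon
signed-rank test with the matched-pairs rank-biserial correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

MIN_N_GATE = 8
RT_SPURIOUS_MS = 100.0


def iqr_outliers(x: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """Boolean mask of points outside the Tukey fences (factor x IQR)."""
    x = np.asarray(x, dtype=float)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - factor * iqr) | (x > q3 + factor * iqr)


def effect_size(differences, kind: str) -> float:
    """Cohen's d or matched-pairs rank-biserial correlation of differences.

    ``cohen_d`` is mean/SD (n-1 denominator).  ``rank_biserial`` is
    1 - 2T/S, with T the sum of the ranks of the negative differences among
    the ranked absolute nonzero differences and S = n(n+1)/2, mapping T
    monotonically onto [-1, 1] (all-positive differences give +1).
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two differences")
    if kind == "cohen_d":
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("Cohen's d undefined: zero-variance differences")
        return float(d.mean() / sd)
    if kind == "rank_biserial":
        nz = d[d != 0]
        if len(nz) == 0:
            raise ValueError("rank-biserial undefined: all differences zero")
        ranks = stats.rankdata(np.abs(nz))
        t_neg = ranks[nz < 0].sum()
        s = len(nz) * (len(nz) + 1) / 2
        return float(1 - 2 * t_neg / s)
    raise ValueError(f"unknown effect size kind {kind!r}")


def gated_paired_test(values_a, values_b=None, alpha: float = 0.05) -> dict:
    """Paired comparison with the normality/outlier test-selection gate.

    Accepts two per-participant arrays (paired) or a single array of
    differences (one-sample against zero).  Returns a dict with the chosen
    ``test_name`` (``paired_t`` or ``wilcoxon``), the statistic, two-tailed
    ``p``, the matching ``effect_size``, and the gate diagnostics.
    """
    a = np.asarray(values_a, dtype=float)
    if values_b is not None:
        b = np.asarray(values_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        diff = a - b
    else:
        diff = a
    if not np.isfinite(diff).all():
        raise ValueError("values must be finite")
    n = len(diff)
    if n < MIN_N_GATE:
        raise ValueError(f"need at least {MIN_N_GATE} pairs for the normality gate")
    if (diff == 0).all():
        return {"test_name": "degenerate", "statistic": float("nan"),
                "p": float("nan"), "effect_size": float("nan"),
                "degenerate": True, "n": n}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p_norm = stats.normaltest(diff)
    has_outliers = bool(iqr_outliers(diff).any())
    parametric = (p_norm > alpha) and not has_outliers
    if parametric:
        if diff.std(ddof=1) == 0:
            return {"test_name": "degenerate", "statistic": float("nan"),
                    "p": float("nan"), "effect_size": float("nan"),
                    "degenerate": True, "n": n}
        t, p = stats.ttest_1samp(diff, 0.0)
        return {"test_name": "paired_t", "statistic": float(t), "p": float(p),
                "effect_size": effect_size(diff, "cohen_d"),
                "effect_size_kind": "cohen_d", "normality_p": float(p_norm),
                "outliers": has_outliers, "degenerate": False, "n": n,
                "mean_difference": float(diff.mean())}
    w, p = stats.wilcoxon(diff)
    return {"test_name": "wilcoxon", "statistic": float(w), "p": float(p),
            "effect_size": effect_size(diff, "rank_biserial"),
            "effect_size_kind": "rank_biserial", "normality_p": float(p_norm),
            "outliers": has_outliers, "degenerate": False, "n": n,
            "mean_difference": float(diff.mean())}


def behavioural_compare(trials: pd.DataFrame, conditions=("word", "nonword")) -> dict:
    """Reaction-time and accuracy comparison between two conditions.

    ``trials`` needs columns ``participant``, ``condition``, ``trial``,
    ``rt_ms`` and ``correct``.  Only the first response per (participant,
    trial) counts; responses faster than 100 ms are discarded as spurious.
    Per participant and condition, the median RT and mean accuracy are
    computed and each is compared across conditions with the gated paired
    test.  Participants lacking valid trials in either condition are
    excluded with a warning.
    """
    required = {"participant", "condition", "trial", "rt_ms", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = trials.drop_duplicates(subset=["participant", "trial"], keep="first")
    df = df[df["rt_ms"] >= RT_SPURIOUS_MS]
    df = df[df["condition"].isin(conditions)]
    if df.empty:
        raise ValueError("no valid trials remain after filtering")

    per = df.groupby(["participant", "condition"]).agg(
        median_rt=("rt_ms", "median"), accuracy=("correct", "mean")).reset_index()
    wide_rt = per.pivot(index="participant", columns="condition", values="median_rt")
    wide_acc = per.pivot(index="participant", columns="condition", values="accuracy")
    complete = wide_rt[list(conditions)].notna().all(axis=1)
    dropped = list(wide_rt.index[~complete])
    if dropped:
        warnings.warn(f"excluding participants without valid trials in both "
                      f"conditions: {dropped}")
    wide_rt, wide_acc = wide_rt[complete], wide_acc[complete]
    a, b = conditions
    return {
        "n_participants": int(complete.sum()),
        "excluded": dropped,
        "rt": gated_paired_test(wide_rt[a].to_numpy(), wide_rt[b].to_numpy()),
        "accuracy": gated_paired_test(wide_acc[a].to_numpy(), wide_acc[b].to_numpy()),
        "median_rt_difference_ms": float((wide_rt[a] - wide_rt[b]).mean()),
        "accuracy_difference": float((wide_acc[a] - wide_acc[b]).mean()),
    }
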