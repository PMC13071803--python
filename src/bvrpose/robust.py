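"""Robust descriptive summaries and nonparametric group comparisons.

Error samples here are absolute helical rotation/translation differences,
pooled across frames and perturbation seeds within a condition.  Spread is
described by the median, limits of agreement (median ± 1.45 × IQR, lower
bound truncated at 0), the unscaled median absolute deviation, and the
cumulative (summed) absolute error.  Outliers use the Hampel identifier in
modified z-score form.  Between-condition inference uses Kruskal–Wallis
with Dunn's post-hoc test under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

LOA_IQR_FACTOR = 1.45
HAMPEL_THRESHOLD = 3.5
MODIFIED_Z_SCALE = 0.6745  # Phi^-1(0.75): makes MAD comparable to sigma


def loa(x, factor: float = LOA_IQR_FACTOR) -> tuple[float, float]:
    """Limits of agreement for absolute errors: ``median ± factor * IQR``
    with a negative lower bound truncated to 0.  IQR uses linear-interpolated
    quantiles."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    med = float(np.median(x))
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    return max(0.0, med - factor * iqr), med + factor * iqr


def mad(x) -> float:
    """Median absolute deviation from the median, unscaled."""
    x = np.asarray(x, float)
    if x.size < 1:
        raise ValueError("need at least 1 observation")
    return float(np.median(np.abs(x - np.median(x))))


def cumulative_error(x) -> float:
    """Sum of absolute deviations from the gold standard."""
    return float(np.abs(np.asarray(x, float)).sum())


def hampel_outliers(x, threshold: float = HAMPEL_THRESHOLD, scaled: bool = True):
    """Boolean outlier mask by the Hampel identifier.

    ``scaled=True`` (default) uses the modified z-score form
    ``0.6745 |x - med| / MAD > threshold``; the unscaled variant drops the
    0.6745 factor.  With zero MAD, exactly the values different from the
    median are flagged.
    """
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    med = np.median(x)
    dev = np.abs(x - med)
    m = np.median(dev)
    if m == 0:
        return dev > 0
    z = dev / m
    if scaled:
        z = MODIFIED_Z_SCALE * z
    return z > threshold


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p-value.

    All-identical data (zero tie-corrected variance) returns (0, 1).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    z: float
    p_adjusted: float


def dunn_posthoc(groups, labels=None, correction: str = "bonferroni"):
    """Dunn's pairwise rank test after Kruskal–Wallis.

    ``z = (Rbar_a - Rbar_b) / sqrt[(N(N+1)/12 - T/(12(N-1)))(1/n_a + 1/n_b)]``
    with tie term ``T = sum(t^3 - t)``; two-sided normal p, Bonferroni-
    adjusted over the number of pairs (capped at 1).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = [
        (i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))
    ]
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        if correction == "bonferroni":
            p = min(1.0, m * p)
        out.append(PairwiseTest(labels[i], labels[j], float(z), float(p)))
    return out


def summarize_errors(x) -> dict:
    """The per-condition descriptive row: median, LOA, cumulative error,
    unscaled MAD, Hampel outlier count and sample size."""
    x = np.asarray(x, float)
    lo, hi = loa(x)
    return {
        "median": float(np.median(x)),
        "loa_low": lo,
        "loa_high": hi,
        "cumulative_error": cumulative_error(x),
        "mad": mad(x),
        "n_outliers": int(hampel_outliers(x).sum()),
        "n": int(x.size),
    }
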