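"""Group-level statistics: summaries, ECDFs, K-S tests, Holm-Sidak.

All statistics are implemented from their standard definitions so the
whole inferential surface of the pipeline is auditable: mean +/- SD group
summaries, right-continuous empirical CDFs, the two-sample
Kolmogorov-Smirnov sup-distance with its asymptotic p-value, the
Holm-Sidak step-down multiple-comparison adjustment, orientation-bin
frequencies, and percent/fold differences between group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "GroupSummary",
    "KSResult",
    "summarize",
    "ecdf",
    "ks_two_sample",
    "holm_sidak",
    "orientation_histogram",
    "percent_difference",
    "fold_change",
    "welch_t_pvalue",
]

ALPHA = 0.05  # significance threshold used throughout


@dataclass(frozen=True)
class GroupSummary:
    group: str
    load: str
    metric: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 1:
            raise ValueError("sd must be >= 0 and n >= 1")


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.D <= 1 and 0 <= self.p <= 1):
            raise ValueError("D and p must lie in [0, 1]")


def summarize(values, group: str, load: str, metric: str) -> GroupSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of one group."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if v.size == 1:
        warnings.warn(
            "single observation: SD reported as 0", stacklevel=2
        )
        return GroupSummary(group, load, metric, float(v[0]), 0.0, 1)
    return GroupSummary(
        group, load, metric, float(v.mean()), float(v.std(ddof=1)), int(v.size)
    )


def ecdf(values) -> pd.DataFrame:
    """Right-continuous ECDF: sorted unique support with cumulative frac."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot build an ECDF from an empty sample")
    support, counts = np.unique(v, return_counts=True)
    return pd.DataFrame(
        {"x": support, "F": np.cumsum(counts) / v.size}
    )


def ks_two_sample(a, b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov sup-distance and asymptotic p-value.

    D is the maximum absolute difference between the two ECDFs over the
    pooled support; p comes from the asymptotic Kolmogorov distribution
    with effective sample size n1*n2/(n1+n2).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(fa - fb)))
    en = a.size * b.size / (a.size + b.size)
    p = float(np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    return KSResult(D=d, p=p, n1=int(a.size), n2=int(b.size))


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sorted ascending, the i-th smallest raw p (1-based) is adjusted to
    1 - (1 - p)^(m - i + 1); monotonicity over the sorted order is
    enforced and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    exponents = m - np.arange(m)
    adj_sorted = 1.0 - (1.0 - p[order]) ** exponents
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


def orientation_histogram(
    angles_norm_deg, bin_width_deg: float = 10.0
) -> pd.DataFrame:
    """Frequencies of absolute normalized orientation per angular bin.

    Bins are [0, 10), [10, 20), ..., [80, 90] degrees by default;
    frequencies are fractions of the fibril count and sum to 1.
    """
    a = np.abs(np.asarray(angles_norm_deg, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    edges = np.arange(0.0, 90.0 + bin_width_deg / 2, bin_width_deg)
    counts, _ = np.histogram(a, bins=edges)
    return pd.DataFrame(
        {
            "bin_lo_deg": edges[:-1],
            "bin_hi_deg": edges[1:],
            "frequency": counts / a.size,
        }
    )


def percent_difference(x: float, ref: float) -> float:
    """100 * (x - ref) / ref."""
    if ref <= 0:
        raise ValueError(f"reference must be > 0, got {ref}")
    return 100.0 * (x - ref) / ref


def fold_change(x: float, ref: float) -> float:
    """x / ref."""
    if ref <= 0:
        raise ValueError(f"reference must be > 0, got {ref}")
    return x / ref


def welch_t_pvalue(a, b) -> float:
    """Two-sided Welch t-test p-value (unequal variances).

    Feeds the Holm-Sidak pairwise comparisons of group means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test needs >= 2 observations per sample")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    denom = va + vb
    if denom == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / np.sqrt(denom)
    df = denom**2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    # regularized incomplete beta gives the two-sided tail of Student's t
    x = df / (df + t**2)
    return float(special.betainc(df / 2.0, 0.5, x))
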