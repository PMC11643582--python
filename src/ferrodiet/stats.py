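"""Statistical layer: Kruskal-Wallis test and the CI half-width rule.

The omnibus group comparison is the Kruskal-Wallis rank test with mid-ranks
for ties, the standard tie correction 1 - sum(t^3 - t) / (N^3 - N), and a
chi-square approximation for the p-value (df = k - 1).

Significance of a projected intake increase uses the "least significant
delta": the half-width z * sd / sqrt(n) of the normal-approximation 95%
confidence interval of a group's mean daily iron intake.  An increase
strictly larger than the half-width is significant at one-sided p < 0.025.
z defaults to 1.96 and is configurable (e.g. to substitute a t quantile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

DEFAULT_Z = 1.96


@dataclass
class KruskalWallisResult:
    h_statistic: float
    df: int
    p_value: float
    tie_correction: float


def kruskal_wallis(groups: list) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H test across ``groups`` of samples.

    H is computed on mid-ranks of the pooled sample, divided by the tie
    correction; the p-value comes from the chi-square approximation with
    df = k - 1.  When every pooled value is identical the tie correction is
    0 and H is defined as 0 (no separation, p = 1).
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis requires non-empty groups")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)

    _, counts = np.unique(pooled, return_counts=True)
    tie_correction = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)

    df = len(groups) - 1
    if tie_correction == 0.0:  # all pooled values identical
        return KruskalWallisResult(0.0, df, 1.0, tie_correction)

    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset : offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    h /= tie_correction
    h = max(h, 0.0)  # guard against negative rounding noise
    return KruskalWallisResult(
        h_statistic=float(h),
        df=df,
        p_value=float(sps.chi2.sf(h, df)),
        tie_correction=float(tie_correction),
    )


def least_significant_delta(sd: float, n: int, z: float = DEFAULT_Z) -> float:
    """Half-width z * sd / sqrt(n) of the group-mean confidence interval (mg/day)."""
    if n < 2:
        raise ValueError(f"least_significant_delta requires n >= 2, got n={n}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    return z * sd / np.sqrt(n)


def flag_significant(delta: float, half_width: float) -> bool:
    """True iff the increase strictly exceeds the CI half-width."""
    return bool(delta > half_width)
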