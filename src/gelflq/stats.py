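"""Inferential statistics for degradation time courses and RIN comparison.

Two procedures cover the analyses the scores feed into: classical one-way
fixed-effects ANOVA with Tukey HSD post-hoc comparisons (Tukey–Kramer for
unequal group sizes) across time points, and ordinary least-squares linear
fits reporting R² and the two-sided slope p-value — used both for
calibration trend lines and for correlating preservation scores with
externally supplied RNA Integrity Numbers (RIN). RIN values are consumed as
inputs only; this package never computes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairwiseComparison",
    "AnovaTukeyResult",
    "LinearFitResult",
    "anova_tukey",
    "linear_fit",
    "significance_stars",
    "read_rin_table",
]


def significance_stars(p: float) -> str:
    """Conventional annotation: p<0.05 '*', p<0.01 '**', p<0.001 '***'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    difference: float  # mean(a) - mean(b)
    p_raw: float  # pooled-variance t-test, unadjusted
    p_adjusted: float  # Tukey HSD (studentized range)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    comparisons: tuple[PairwiseComparison, ...]


@dataclass(frozen=True)
class LinearFitResult:
    slope: float
    intercept: float
    r2: float
    p: float  # two-sided p-value of the slope, t distribution with n-2 df


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA followed by Tukey HSD.

    ``groups`` maps a label (e.g. time point) to its replicate measurements;
    at least two groups with at least two replicates each are required.
    Unequal group sizes use the Tukey–Kramer extension. The unadjusted
    pairwise p-values (pooled-variance t-tests on the ANOVA's within-group
    mean square) are reported alongside the Tukey-adjusted ones.
    """
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    for k, arr in zip(labels, data):
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 replicate measurements")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {k!r} contains non-finite values")
    n_total = sum(a.size for a in data)
    df_within = n_total - len(data)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in data)
    if ss_within <= 0:
        raise ValueError("zero within-group variance in every group; F is undefined")

    f_stat, p_val = sps.f_oneway(*data)
    tukey = sps.tukey_hsd(*data)

    mse = ss_within / df_within
    comparisons = []
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            diff = float(data[i].mean() - data[j].mean())
            se = np.sqrt(mse * (1.0 / data[i].size + 1.0 / data[j].size))
            t = diff / se
            p_raw = float(2.0 * sps.t.sf(abs(t), df_within))
            comparisons.append(
                PairwiseComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    difference=diff,
                    p_raw=p_raw,
                    p_adjusted=float(tukey.pvalue[i, j]),
                )
            )
    return AnovaTukeyResult(
        f_statistic=float(f_stat), p_value=float(p_val), comparisons=tuple(comparisons)
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFitResult:
    """OLS line with R² and slope p-value.

    R² is the squared correlation of the OLS fit — the convention used when
    reporting score-versus-RIN correlations — not a Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"x and y lengths differ: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need >= 3 points for a slope p-value")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the slope is undefined")
    fit = sps.linregress(x, y)
    return LinearFitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
    )


def read_rin_table(path) -> dict[str, float]:
    """Read externally measured RIN values from a two-column CSV.

    Expected columns: condition label, RIN. A header row is detected and
    skipped when its second field is non-numeric.
    """
    import csv

    out: dict[str, float] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise ValueError(f"{path}: empty RIN table")
    start = 0
    try:
        float(rows[0][1])
    except (ValueError, IndexError):
        start = 1
    for r, row in enumerate(rows[start:], start=start):
        if len(row) < 2:
            raise ValueError(f"{path}: row {r + 1} has fewer than 2 columns")
        out[row[0].strip()] = float(row[1])
    return out
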