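"""Molecular-weight calibration from a ladder lane.

Migration distance in an agarose gel is, to good approximation, linear in
the logarithm of fragment size, so under the bottom-indexed convention the
size at lane index x follows the exponential law

    size(x) = a * exp(b * x),        a > 0 [nt], b > 0 [per index].

The ladder lane's band positions are detected by prominence, paired with
the manufacturer-declared band sizes (always user-supplied, never
inferred), and the law is fitted by ordinary least squares of ln(size) on
index. R² is reported on that log scale. Peak-shift metrics express how far
a sample's dominant product moved relative to the control, both as a size
difference (nt) and as a size ratio.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.signal import peak_prominences

from .model import LadderCalibration, LaneProfile, PeakShift
from .zoning import prominent_maxima

__all__ = [
    "detect_ladder_bands",
    "fit_exponential_calibration",
    "mw_at_index",
    "index_of_size",
    "is_extrapolated",
    "peak_shift_metrics",
]


def detect_ladder_bands(
    ladder: LaneProfile, n_bands: int, min_separation: int = 8
) -> list[int]:
    """Indexes of the ``n_bands`` most prominent ladder maxima, ascending.

    Expects a background-corrected ladder profile. Maxima closer than
    ``min_separation`` to a more prominent one are skipped.
    """
    if n_bands < 2:
        raise ValueError("need at least 2 bands to calibrate")
    maxima = prominent_maxima(ladder.values, min_separation)
    if len(maxima) < n_bands:
        raise ValueError(
            f"lane {ladder.label!r}: found only {len(maxima)} qualifying maxima, "
            f"need {n_bands}"
        )
    values = ladder.values
    proms = peak_prominences(values, np.asarray(maxima))[0]
    keep = np.asarray(maxima)[np.argsort(proms)[::-1][:n_bands]]
    return sorted(int(i) for i in keep)


def fit_exponential_calibration(
    band_indices: Sequence[float],
    band_sizes: Sequence[float],
    nonlinear: bool = False,
) -> LadderCalibration:
    """Fit ``size = a * exp(b * index)`` to ladder band positions.

    The default fit is ordinary least squares of ln(size) on index — the
    standard, numerically stable estimator for a log-linear migration law —
    with R² reported on the log scale. ``nonlinear=True`` refines (a, b)
    with a direct least-squares fit on the size scale (for sensitivity
    checks); R² is still the log-scale coefficient of determination.
    """
    idx = np.asarray(band_indices, dtype=float)
    sizes = np.asarray(band_sizes, dtype=float)
    if idx.size != sizes.size:
        raise ValueError(f"{idx.size} indices vs {sizes.size} sizes")
    if idx.size < 2:
        raise ValueError("need >= 2 ladder bands")
    if np.any(sizes <= 0):
        raise ValueError("band sizes must be positive")
    order = np.argsort(idx)
    idx, sizes = idx[order], sizes[order]
    if np.any(np.diff(idx) <= 0):
        raise ValueError("duplicate band indexes — ladder misread")
    if np.any(np.diff(sizes) <= 0):
        raise ValueError(
            "band sizes must increase with index (ladder misread or wrong orientation)"
        )
    log_sizes = np.log(sizes)
    if idx.size == 2:
        b = (log_sizes[1] - log_sizes[0]) / (idx[1] - idx[0])
        intercept = log_sizes[0] - b * idx[0]
        r2 = 1.0
    else:
        fit = stats.linregress(idx, log_sizes)
        b, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    a = float(np.exp(intercept))
    if b <= 0:
        raise ValueError(f"fitted rate b = {b:.4g} is not positive — ladder misread")
    if nonlinear:
        popt, _ = optimize.curve_fit(lambda x, a_, b_: a_ * np.exp(b_ * x), idx, sizes, p0=(a, b))
        a, b = float(popt[0]), float(popt[1])
    return LadderCalibration(
        a=a,
        b=float(b),
        r2=min(r2, 1.0),
        band_indices=tuple(float(i) for i in idx),
        band_sizes=tuple(float(s) for s in sizes),
    )


def mw_at_index(cal: LadderCalibration, i: float) -> float:
    """Size in nt at lane index ``i``: ``a * exp(b * i)``."""
    if i < 0:
        raise ValueError("index must be >= 0")
    return float(cal.a * np.exp(cal.b * i))


def index_of_size(cal: LadderCalibration, size: float) -> float:
    """Closed-form inverse of :func:`mw_at_index`: ``ln(size / a) / b``."""
    if size <= 0:
        raise ValueError("size must be positive")
    return float(np.log(size / cal.a) / cal.b)


def is_extrapolated(cal: LadderCalibration, i: float) -> bool:
    """True when ``i`` lies outside the fitted ladder band range.

    Extrapolation (e.g. degraded fragments below the smallest ladder band)
    is permitted but should be flagged in reported results.
    """
    lo, hi = cal.index_range
    return not (lo <= i <= hi)


def peak_shift_metrics(
    sample_peak: int, control_peak: int, cal: LadderCalibration
) -> PeakShift:
    """Peak shift of a sample's lane maximum relative to the control.

    Returns both the size difference (control minus sample, nt — positive
    under degradation) and the sample/control size ratio.
    """
    return PeakShift(
        mw_sample=mw_at_index(cal, sample_peak),
        mw_control=mw_at_index(cal, control_peak),
    )
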