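"""Partition a corrected lane into product-peak and degradation zones.

The dominant product appears as the lane's global intensity maximum; the
peak zone is the fixed-width window of indexes surrounding that maximum
(20 by default, implemented as the half-open window ``[m-10, m+10)``).
Everything below it toward the gel bottom — fragments that migrated
further — is the degradation zone. Zone signal is integrated by the
trapezoidal rule with unit index spacing.

Total-RNA lanes carry two ribosomal peaks (18S and 28S); each gets its own
peak window, with the 28S degradation zone running from the end of the 18S
window up to the start of the 28S window, and the 18S degradation zone from
the floor index up to the 18S window.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .model import LanePartition, LaneProfile, ZoneWindow

__all__ = [
    "find_global_peak",
    "peak_window",
    "degradation_window",
    "area_under_curve",
    "partition_two_peaks",
    "partition_single_peak",
    "prominent_maxima",
]

#: Default width of the product-peak window, in indexes.
DEFAULT_PEAK_WIDTH = 20


def prominent_maxima(values: np.ndarray, min_separation: int) -> list[int]:
    """Local maxima accepted greedily by decreasing prominence.

    All strict local maxima are located and ranked by prominence (height
    above the higher of the two flanking minima); maxima closer than
    ``min_separation`` indexes to an already-accepted, more prominent
    maximum are skipped. Returned sorted ascending by index.
    """
    values = np.asarray(values, dtype=float)
    peaks, _ = find_peaks(values)
    if peaks.size == 0:
        return []
    prominences = peak_prominences(values, peaks)[0]
    accepted: list[int] = []
    for k in np.argsort(prominences)[::-1]:
        idx = int(peaks[k])
        if all(abs(idx - a) >= min_separation for a in accepted):
            accepted.append(idx)
    return sorted(accepted)


def find_global_peak(profile: LaneProfile, search: Optional[ZoneWindow] = None) -> int:
    """Index of the maximum gray value (ties broken by the smallest index)."""
    values = profile.values
    lo, hi = 0, values.size
    if search is not None:
        if not (0 <= search.start < search.end <= values.size):
            raise ValueError(f"search window [{search.start}, {search.end}) out of bounds")
        lo, hi = search.start, search.end
    segment = values[lo:hi]
    if np.all(segment == 0):
        raise ValueError(f"lane {profile.label!r}: no signal above background")
    return lo + int(np.argmax(segment))


def peak_window(peak_index: int, profile_length: int, width: int = DEFAULT_PEAK_WIDTH) -> ZoneWindow:
    """Fixed-width window of indexes surrounding the maximum.

    The window is ``[peak - width//2, peak + width - width//2)`` clipped to
    the profile; near an edge it simply gets shorter (no re-expansion on the
    other side).
    """
    if not (0 <= peak_index < profile_length):
        raise ValueError(f"peak index {peak_index} outside [0, {profile_length})")
    if width < 1:
        raise ValueError("window width must be >= 1")
    half = width // 2
    start = max(0, peak_index - half)
    end = min(profile_length, peak_index + (width - half))
    return ZoneWindow(start=start, end=end, kind="peak")


def degradation_window(peak: ZoneWindow, floor_index: int = 0) -> ZoneWindow:
    """Degradation zone ``[floor_index, peak.start)`` below a peak window.

    Empty (zero AUC) when the peak window reaches the floor. The floor
    defaults to the gel bottom; raise it to exclude primer or dye fronts.
    """
    if floor_index > peak.start:
        raise ValueError(f"floor_index {floor_index} exceeds peak window start {peak.start}")
    return ZoneWindow(start=floor_index, end=peak.start, kind="degradation")


def area_under_curve(profile: LaneProfile, window: ZoneWindow) -> float:
    """Trapezoidal integral of the profile over ``[start, end)``, unit spacing.

    A window with fewer than two samples has zero area.
    """
    if window.end > len(profile):
        raise ValueError(f"window [{window.start}, {window.end}) exceeds profile of length {len(profile)}")
    if len(window) < 2:
        return 0.0
    return float(np.trapezoid(profile.values[window.start : window.end]))


def partition_single_peak(
    profile: LaneProfile,
    width: int = DEFAULT_PEAK_WIDTH,
    floor_index: int = 0,
) -> LanePartition:
    """Single-product partition: one peak window plus its degradation zone.

    Signal above the peak window (toward the well) is integrated separately
    as ``high_mw_auc``; it enters no score by default but is useful for
    doublet products.
    """
    m = find_global_peak(profile)
    pw = peak_window(m, len(profile), width)
    dw = degradation_window(pw, floor_index)
    high = ZoneWindow(start=pw.end, end=len(profile), kind="degradation")
    return LanePartition(
        label=profile.label,
        peak_windows=(pw,),
        degradation_windows=(dw,),
        peak_aucs=(area_under_curve(profile, pw),),
        degradation_aucs=(area_under_curve(profile, dw),),
        high_mw_auc=area_under_curve(profile, high) if len(high) >= 2 else 0.0,
    )


def partition_two_peaks(
    profile: LaneProfile,
    min_separation: int = 20,
    width: int = DEFAULT_PEAK_WIDTH,
    floor_index: int = 0,
) -> LanePartition:
    """Total-RNA partition around the two most prominent maxima.

    Prominence-ranked local maxima at least ``min_separation`` indexes apart
    are located; the two most prominent are taken as 18S (lower index) and
    28S (higher index). Each receives a ``width``-index peak window; the 28S
    degradation window spans from the end of the 18S window to the start of
    the 28S window, the 18S degradation window from ``floor_index`` to the
    18S window.
    """
    values = profile.values
    maxima = prominent_maxima(values, min_separation)
    if len(maxima) < 2:
        raise ValueError(
            f"lane {profile.label!r}: found {len(maxima)} qualifying maxima, need 2; "
            "use the single-peak pathway for single-product lanes"
        )
    # the two most prominent among the accepted maxima
    top_two = sorted(
        maxima,
        key=lambda i: -peak_prominences(values, np.array([i]))[0][0],
    )[:2]
    p18, p28 = sorted(int(i) for i in top_two)

    w18 = peak_window(p18, values.size, width)
    w28 = peak_window(p28, values.size, width)
    if w18.end > w28.start:
        raise ValueError(
            f"lane {profile.label!r}: peak windows [{w18.start},{w18.end}) and "
            f"[{w28.start},{w28.end}) overlap; increase min_separation or reduce width"
        )
    d18 = degradation_window(w18, floor_index)
    d28 = ZoneWindow(start=w18.end, end=w28.start, kind="degradation")
    high = ZoneWindow(start=w28.end, end=values.size, kind="degradation")
    return LanePartition(
        label=profile.label,
        peak_windows=(w18, w28),
        degradation_windows=(d18, d28),
        peak_aucs=(area_under_curve(profile, w18), area_under_curve(profile, w28)),
        degradation_aucs=(area_under_curve(profile, d18), area_under_curve(profile, d28)),
        high_mw_auc=area_under_curve(profile, high) if len(high) >= 2 else 0.0,
    )
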