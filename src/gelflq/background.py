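"""Background-gradient estimation and subtraction.

Agarose gel images carry a roughly linear intensity gradient along the
migration axis (brighter toward the wells). Because full-lane scoring
compares signal across the whole lane, this gradient must be removed
index-wise before any area is integrated. Two estimators are provided:

* ``background_from_lanes`` — measure a blank lane, or average several
  narrow inter-lane strips; the raw per-index mean is subtracted and an OLS
  line is fitted for diagnostics.
* ``background_computed`` — when no blank lane exists, interpolate linearly
  between the mean gray values of the bottom and top edges of a reference
  (usually control) lane; the interpolated line is subtracted.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .model import BackgroundModel, LaneProfile

__all__ = ["background_from_lanes", "background_computed", "subtract_background"]


def background_from_lanes(lanes: list[LaneProfile]) -> BackgroundModel:
    """Measured background: pointwise mean of blank-lane/strip profiles.

    The slope/intercept of an ordinary least-squares line fitted to the mean
    values versus index are reported so the downward trend of the gradient
    can be inspected, but the raw per-index values are what downstream
    subtraction uses.
    """
    if not lanes:
        raise ValueError("at least one background lane is required")
    lengths = {len(p) for p in lanes}
    if len(lengths) != 1:
        raise ValueError(f"background lanes must have equal length, got {sorted(lengths)}")
    if 1 < len(lanes) < 3:
        warnings.warn(
            "fewer than 3 inter-lane strips supplied; the averaged background "
            "may be noisy",
            stacklevel=2,
        )
    values = np.mean([p.values for p in lanes], axis=0)
    x = np.arange(values.size, dtype=float)
    fit = stats.linregress(x, values)
    return BackgroundModel(
        kind="measured", values=values, slope=float(fit.slope), intercept=float(fit.intercept)
    )


def background_computed(reference: LaneProfile, edge_fraction: float = 0.05) -> BackgroundModel:
    """Computed background from the top and bottom of a reference lane.

    The bottom value is the mean over the lowest ``edge_fraction`` of
    indexes, the top value the mean over the highest; the background is the
    straight line through those two means, each anchored at its segment's
    centre index (so a perfectly linear gradient is reproduced without
    bias). Keep the edge fraction small enough that no band sits inside
    either edge segment.
    """
    if not (0.0 < edge_fraction <= 0.25):
        raise ValueError(f"edge_fraction must be in (0, 0.25], got {edge_fraction}")
    n = len(reference)
    if n < 2.0 / edge_fraction:
        raise ValueError(
            f"reference lane of length {n} too short for edge_fraction {edge_fraction} "
            f"(need >= {int(np.ceil(2.0 / edge_fraction))})"
        )
    n_edge = max(1, int(round(edge_fraction * n)))
    bottom_value = float(reference.values[:n_edge].mean())
    top_value = float(reference.values[-n_edge:].mean())
    bottom_centre = (n_edge - 1) / 2.0
    top_centre = (n - 1) - bottom_centre
    slope = (top_value - bottom_value) / (top_centre - bottom_centre)
    intercept = bottom_value - slope * bottom_centre
    values = intercept + slope * np.arange(n)
    return BackgroundModel(kind="computed", values=values, slope=slope, intercept=intercept)


def subtract_background(profile: LaneProfile, model: BackgroundModel) -> LaneProfile:
    """Index-wise background subtraction, floored at zero.

    ``out[i] = max(0, profile[i] - model.values[i])``. Stain fluorescence
    cannot be negative and downstream AUCs must be non-negative, so
    over-subtracted indexes are clipped to 0.
    """
    if len(profile) != model.values.size:
        raise ValueError(
            f"length mismatch: profile {len(profile)} vs background {model.values.size}"
        )
    corrected = np.maximum(profile.values - model.values, 0.0)
    return profile.with_values(corrected, label=f"{profile.label} (corrected)")
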