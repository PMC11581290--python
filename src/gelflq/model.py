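"""Core data model shared across the full-lane quantification pipeline.

Conventions used throughout the package:

* Lane profiles are indexed from the **bottom** of the gel: index 0 is the
  migration front (smallest fragments), the last index is the well side.
* Intensities are in arbitrary units (AU), the gray values of the gel image.
* Areas under the curve (AUC) are in AU·index, computed with unit spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "EDGES",
    "GelImage",
    "LaneProfile",
    "GelRun",
    "BackgroundModel",
    "ZoneWindow",
    "LanePartition",
    "LadderCalibration",
    "PeakShift",
    "ScoreRecord",
]

#: Valid image edge labels; the gel bottom (migration front) is one of these.
EDGES = ("top", "bottom", "left", "right")


@dataclass(frozen=True)
class GelImage:
    """A grayscale gel image: light bands on a dark background.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer gray values (AU).
    bit_depth
        8 or 16; every pixel must lie in ``[0, 2**bit_depth - 1]``.
    bottom_edge
        Which image edge corresponds to the gel bottom (the migration
        front). One of ``"top"``, ``"bottom"``, ``"left"``, ``"right"``.
    """

    pixels: np.ndarray
    bit_depth: int
    bottom_edge: str = "bottom"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D matrix")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.bottom_edge not in EDGES:
            raise ValueError(f"bottom_edge must be one of {EDGES}, got {self.bottom_edge!r}")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"pixel values outside [0, {2**self.bit_depth - 1}] for bit depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class LaneProfile:
    """Ordered gray values for one lane, index 0 = gel bottom."""

    label: str
    values: np.ndarray
    source: str = "workbook-column"  # "image-box", "workbook-column" or "synthetic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError(f"lane {self.label!r}: values must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"lane {self.label!r}: values contain non-finite entries")
        if v.min() < 0:
            raise ValueError(f"lane {self.label!r}: raw gray values must be non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, label: Optional[str] = None) -> "LaneProfile":
        return LaneProfile(label if label is not None else self.label, values, self.source)


@dataclass
class GelRun:
    """One gel's set of lane profiles.

    ``samples`` is an ordered mapping from condition label (e.g. time point)
    to the lane profile. All profiles must have identical length, matching
    the shared measurement box of the acquisition protocol.
    """

    gel_id: str
    date: str
    ladder: Optional[LaneProfile]
    background_lanes: list[LaneProfile]
    control: Optional[LaneProfile]
    samples: dict[str, LaneProfile]

    def __post_init__(self) -> None:
        lanes = list(self.iter_profiles())
        if not lanes:
            raise ValueError("GelRun must contain at least one lane")
        lengths = {len(p) for _, p in lanes}
        if len(lengths) != 1:
            raise ValueError(f"all profiles must have identical length, got lengths {sorted(lengths)}")
        labels = [label for label, _ in lanes]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique within a gel run")

    def iter_profiles(self):
        """Yield (label, profile) for every lane present, ladder first."""
        if self.ladder is not None:
            yield ("ladder", self.ladder)
        for i, p in enumerate(self.background_lanes):
            yield (f"background_{i}", p)
        if self.control is not None:
            yield ("control", self.control)
        yield from self.samples.items()

    @property
    def lane_length(self) -> int:
        return len(next(iter(self.iter_profiles()))[1])


@dataclass(frozen=True)
class BackgroundModel:
    """Per-index background of the gel along the migration axis.

    ``kind`` is ``"measured"`` (blank lane / inter-lane strips) or
    ``"computed"`` (linear interpolation between the top and bottom edge
    means of a reference lane). ``values`` is what gets subtracted;
    ``slope``/``intercept`` describe the fitted linear trend (AU per index,
    AU at index 0) and are diagnostic for the measured kind.
    """

    kind: str
    values: np.ndarray
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.kind not in ("measured", "computed"):
            raise ValueError(f"kind must be 'measured' or 'computed', got {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0 or not np.all(np.isfinite(v)):
            raise ValueError("background values must be a finite non-empty 1-D array")
        object.__setattr__(self, "values", np.maximum(v, 0.0))


@dataclass(frozen=True)
class ZoneWindow:
    """Half-open index window ``[start, end)`` on a lane profile."""

    start: int
    end: int
    kind: str  # "peak" or "degradation"

    def __post_init__(self) -> None:
        if self.kind not in ("peak", "degradation"):
            raise ValueError(f"kind must be 'peak' or 'degradation', got {self.kind!r}")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def is_empty(self) -> bool:
        return self.end == self.start


@dataclass(frozen=True)
class LanePartition:
    """Peak and degradation zones of one corrected lane plus their AUCs.

    Single-product lanes carry one peak window; total-RNA lanes carry two
    (18S at the lower index, 28S at the higher index). ``degradation_windows``
    is parallel to ``peak_windows``.
    """

    label: str
    peak_windows: tuple[ZoneWindow, ...]
    degradation_windows: tuple[ZoneWindow, ...]
    peak_aucs: tuple[float, ...]
    degradation_aucs: tuple[float, ...]
    high_mw_auc: float = 0.0

    def __post_init__(self) -> None:
        if len(self.peak_windows) != len(self.degradation_windows):
            raise ValueError("peak and degradation windows must be parallel")
        if len(self.peak_aucs) != len(self.peak_windows) or len(self.degradation_aucs) != len(
            self.peak_windows
        ):
            raise ValueError("AUC tuples must be parallel to the windows")
        if any(a < 0 for a in self.peak_aucs + self.degradation_aucs):
            raise ValueError("AUCs must be non-negative")
        windows = sorted(
            [w for w in self.peak_windows + self.degradation_windows if not w.is_empty],
            key=lambda w: w.start,
        )
        for a, b in zip(windows, windows[1:]):
            if a.end > b.start:
                raise ValueError(f"windows overlap: [{a.start},{a.end}) and [{b.start},{b.end})")


@dataclass(frozen=True)
class LadderCalibration:
    """Exponential size calibration ``size = a * exp(b * index)``.

    Fitted by ordinary least squares of ln(size) on band index; ``r2`` is the
    coefficient of determination of that log-scale regression. Under the
    bottom-indexed convention both ``a`` (nt) and ``b`` (per index) are
    positive: size grows toward the well.
    """

    a: float
    b: float
    r2: float
    band_indices: tuple[float, ...]
    band_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"calibration requires a > 0 and b > 0, got a={self.a}, b={self.b}")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")
        idx = np.asarray(self.band_indices, dtype=float)
        sizes = np.asarray(self.band_sizes, dtype=float)
        if idx.size != sizes.size or idx.size < 2:
            raise ValueError("need >= 2 (index, size) pairs")
        if np.any(np.diff(idx) <= 0) or np.any(np.diff(sizes) <= 0):
            raise ValueError("band indices and sizes must be strictly increasing together")

    @property
    def index_range(self) -> tuple[float, float]:
        return (self.band_indices[0], self.band_indices[-1])


@dataclass(frozen=True)
class PeakShift:
    """Molecular-weight change of the lane maximum relative to control."""

    mw_sample: float
    mw_control: float

    @property
    def shift(self) -> float:
        """nt; positive when the sample peak migrated to a smaller size."""
        return self.mw_control - self.mw_sample

    @property
    def ratio(self) -> float:
        """mw_sample / mw_control, dimensionless."""
        return self.mw_sample / self.mw_control


@dataclass(frozen=True)
class ScoreRecord:
    """Per-lane quantification result.

    ``peak_aucs`` / ``degradation_aucs`` hold one entry for single-product
    lanes and two (18S, 28S) for total RNA. ``*_norm`` values are fold
    changes relative to the control lane; by construction the control's
    normalized values, preservation_norm and combined_norm are exactly 1.
    """

    condition: str
    peak_aucs: tuple[float, ...]
    degradation_aucs: tuple[float, ...]
    peak_aucs_norm: tuple[float, ...]
    degradation_aucs_norm: tuple[float, ...]
    preservation_raw: float
    preservation_norm: float
    combined_norm: float
    high_mw_auc: float = 0.0
    mw_max: Optional[float] = None
    mw_extrapolated: bool = False
    peak_shift: Optional[PeakShift] = None
    peak_index: Optional[int] = None
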