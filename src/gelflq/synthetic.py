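"""Synthetic gels with known ground truth.

The generator emulates the phenomenology the analysis pipeline assumes:

* bands are Gaussian bumps centred at the index the exponential migration
  law assigns to their size;
* degradation moves a fraction of each band's mass (``smear_fraction``)
  into a low-molecular-weight smear spanning the lane below the band,
  densest at the migration front and decaying exponentially toward the
  band, so total stain mass is conserved as a product degrades and a fully
  degraded lane no longer peaks at the product position;
* a linear background gradient runs from the gel bottom (dim) to the top
  (bright), as gel-documentation images show;
* additive Gaussian pixel noise, floored at zero.

All randomness flows from the seed carried by the specs; per-lane seeds are
derived deterministically (base seed + lane ordinal), so any gel can be
regenerated exactly. Default parameter values reproduce the design of a
10-day IVT-mRNA degradation experiment: a ~2.1 knt single product run with
a ladder lane, a blank background lane, a day-0 control and later time
points, in triplicate, on a gel whose background rises from 0 AU at the
bottom to 400 AU at the top on the 16-bit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import index_of_size
from .model import GelImage, GelRun, LadderCalibration, LaneProfile

__all__ = [
    "LaneSpec",
    "TimePoint",
    "ExperimentSpec",
    "GelGeometry",
    "calibration_from_law",
    "synth_profile",
    "synth_gel_image",
    "synth_experiment",
    "DEFAULT_LADDER_SIZES",
    "gaussian_band_mass",
]

#: Declared sizes (nt) of the simulated RNA ladder, smallest first.
DEFAULT_LADDER_SIZES = (500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0, 4000.0, 5000.0, 6000.0, 9000.0)

#: Migration-law parameters of the simulated gels: size = A * exp(B * index).
DEFAULT_LAW_A = 74.215
DEFAULT_LAW_B = 0.013


def calibration_from_law(
    a: float = DEFAULT_LAW_A,
    b: float = DEFAULT_LAW_B,
    ladder_sizes: Sequence[float] = DEFAULT_LADDER_SIZES,
) -> LadderCalibration:
    """Exact calibration object for a generator migration law."""
    sizes = tuple(sorted(float(s) for s in ladder_sizes))
    indices = tuple(float(np.log(s / a) / b) for s in sizes)
    return LadderCalibration(a=a, b=b, r2=1.0, band_indices=indices, band_sizes=sizes)


def gaussian_band_mass(amplitude: float, sigma: float) -> float:
    """Analytic area of a Gaussian band: amplitude * sigma * sqrt(2*pi)."""
    return float(amplitude * sigma * np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class LaneSpec:
    """Ground-truth description of one synthetic lane.

    ``band_amplitudes`` are peak heights (AU) before any mass is lost to the
    smear; a band of amplitude A and width sigma carries total mass
    ``A * sigma * sqrt(2*pi)`` AU·index, split ``(1 - smear_fraction)`` into
    the Gaussian band and ``smear_fraction`` into the smear below it.
    ``smear_decay`` sets the smear's per-index exponential fall-off from the
    migration front up toward the band.
    """

    band_sizes: tuple[float, ...] = ()
    band_amplitudes: tuple[float, ...] = ()
    band_sigma: float = 3.0
    smear_fraction: float = 0.0
    smear_decay: float = 0.02
    background_top: float = 400.0
    background_bottom: float = 0.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.band_sizes) != len(self.band_amplitudes):
            raise ValueError("band_sizes and band_amplitudes must be parallel")
        if not (0.0 <= self.smear_fraction <= 1.0):
            raise ValueError("smear_fraction must be in [0, 1]")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.smear_decay <= 0:
            raise ValueError("smear_decay must be positive")


def _lane_signal(spec: LaneSpec, cal: LadderCalibration, length: int) -> np.ndarray:
    """Noise-free band + smear signal (no background)."""
    idx = np.arange(length, dtype=float)
    signal = np.zeros(length)
    for size, amp in zip(spec.band_sizes, spec.band_amplitudes):
        centre = index_of_size(cal, size)
        signal += (1.0 - spec.smear_fraction) * amp * np.exp(
            -((idx - centre) ** 2) / (2.0 * spec.band_sigma**2)
        )
        if spec.smear_fraction > 0:
            lo = int(np.floor(centre)) + 1
            tail_idx = np.arange(max(lo, 1), dtype=float)  # indexes [0, centre]
            if tail_idx.size:
                # densest at the migration front, decaying toward the band
                weights = np.exp(-spec.smear_decay * tail_idx)
                weights /= weights.sum()
                smear_mass = spec.smear_fraction * gaussian_band_mass(amp, spec.band_sigma)
                signal[: tail_idx.size] += smear_mass * weights
    return signal


def synth_profile(spec: LaneSpec, cal: LadderCalibration, length: int) -> LaneProfile:
    """One lane profile: bands + smear + linear background + noise.

    Deterministic for a fixed ``spec.seed``. Values are floored at 0, as
    gray values are.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(spec.seed)
    background = np.linspace(spec.background_bottom, spec.background_top, length)
    values = _lane_signal(spec, cal, length) + background
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, length)
    return LaneProfile(label=f"synthetic(seed={spec.seed})", values=np.maximum(values, 0.0), source="synthetic")


@dataclass(frozen=True)
class GelGeometry:
    """Pixel geometry of a synthetic gel image (migration along rows)."""

    lane_width: int = 12
    gap: int = 6
    length: int = 420

    def __post_init__(self) -> None:
        if min(self.lane_width, self.gap) < 1 or self.length < 2:
            raise ValueError("lane_width and gap must be >= 1 pixel, length >= 2")

    def lane_origin_col(self, i: int) -> int:
        return self.gap + i * (self.lane_width + self.gap)

    def image_width(self, n_lanes: int) -> int:
        return self.gap + n_lanes * (self.lane_width + self.gap)


def synth_gel_image(
    lane_specs: Sequence[LaneSpec],
    geometry: GelGeometry,
    cal: LadderCalibration,
    seed: int = 0,
) -> GelImage:
    """Render lanes into a 16-bit gel image, bottom edge at the bottom.

    Each lane's columns carry that lane's noise-free signal plus the shared
    background gradient; inter-lane gaps carry background only. Per-pixel
    Gaussian noise with the first spec's ``noise_sd`` is added from ``seed``
    and the result is rounded to integers, so the column-mean profile of a
    lane equals its :func:`synth_profile` signal up to pixel noise (and to
    within 0.5 AU of rounding when noise is zero).
    """
    if not lane_specs:
        raise ValueError("need at least one lane spec")
    length = geometry.length
    width = geometry.image_width(len(lane_specs))
    base = lane_specs[0]
    background = np.linspace(base.background_bottom, base.background_top, length)
    # image rows run top -> bottom; profile index 0 = gel bottom = last row
    img = np.tile(background[::-1][:, None], (1, width))
    for i, spec in enumerate(lane_specs):
        c0 = geometry.lane_origin_col(i)
        signal = _lane_signal(spec, cal, length)
        img[:, c0 : c0 + geometry.lane_width] += signal[::-1][:, None]
    rng = np.random.default_rng(seed)
    if base.noise_sd > 0:
        img = img + rng.normal(0.0, base.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return GelImage(pixels=pixels, bit_depth=16, bottom_edge="bottom")


@dataclass(frozen=True)
class TimePoint:
    """One condition lane of a degradation experiment.

    ``band_sizes`` are the ground-truth dominant product sizes for that
    time point (one entry for IVT mRNA, two for total RNA);
    ``amplitude_scale`` multiplies the base band amplitude to emulate
    overall signal loss.
    """

    label: str
    band_sizes: tuple[float, ...]
    smear_fraction: float
    amplitude_scale: float = 1.0


def _default_timepoints() -> tuple[TimePoint, ...]:
    # 37 degC IVT-mRNA time course: dominant product sizes follow the
    # measured single-product degradation trajectory (~2.1 knt product
    # collapsing to ~0.6 knt fragments by day 7).
    return (
        TimePoint("control", (2118.90,), 0.05, 1.00),
        TimePoint("day2", (2171.19,), 0.15, 0.90),
        TimePoint("day4", (2087.07,), 0.30, 0.80),
        TimePoint("day7", (630.90,), 0.55, 0.65),
        TimePoint("day10", (569.40,), 0.70, 0.55),
    )


@dataclass(frozen=True)
class ExperimentSpec:
    """Full degradation experiment: replicated gels with known truth."""

    law_a: float = DEFAULT_LAW_A
    law_b: float = DEFAULT_LAW_B
    lane_length: int = 420
    ladder_sizes: tuple[float, ...] = DEFAULT_LADDER_SIZES
    timepoints: tuple[TimePoint, ...] = field(default_factory=_default_timepoints)
    replicates: int = 3
    base_seed: int = 0
    band_amplitude: float = 2000.0
    band_sigma: float = 3.0
    smear_decay: float = 0.02
    background_top: float = 400.0
    background_bottom: float = 0.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")
        if not self.timepoints:
            raise ValueError("need >= 1 time point")
        fracs = [tp.smear_fraction for tp in self.timepoints]
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("smear_fraction must be non-decreasing over time points")

    @property
    def calibration(self) -> LadderCalibration:
        return calibration_from_law(self.law_a, self.law_b, self.ladder_sizes)


def synth_experiment(spec: ExperimentSpec) -> tuple[list[GelRun], pd.DataFrame]:
    """Generate one GelRun per replicate plus a ground-truth table.

    Each gel carries a ladder lane, a blank background lane, the control
    (first time point) and one lane per later time point. The truth table
    records, per lane, the programmed smear fraction, band sizes and
    centres, and the analytic Gaussian/smear masses.
    """
    cal = spec.calibration
    runs: list[GelRun] = []
    truth_rows: list[dict] = []
    for rep in range(spec.replicates):
        seed0 = spec.base_seed + 1000 * rep
        common = dict(
            band_sigma=spec.band_sigma,
            smear_decay=spec.smear_decay,
            background_top=spec.background_top,
            background_bottom=spec.background_bottom,
            noise_sd=spec.noise_sd,
        )
        ladder_spec = LaneSpec(
            band_sizes=tuple(spec.ladder_sizes),
            band_amplitudes=tuple(spec.band_amplitude for _ in spec.ladder_sizes),
            seed=seed0,
            **common,
        )
        blank_spec = LaneSpec(seed=seed0 + 1, **common)
        lanes: dict[str, LaneProfile] = {}
        for ordinal, tp in enumerate(spec.timepoints, start=2):
            amp = spec.band_amplitude * tp.amplitude_scale
            lane_spec = LaneSpec(
                band_sizes=tp.band_sizes,
                band_amplitudes=tuple(amp for _ in tp.band_sizes),
                smear_fraction=tp.smear_fraction,
                seed=seed0 + ordinal,
                **common,
            )
            prof = synth_profile(lane_spec, cal, spec.lane_length)
            lanes[tp.label] = prof.with_values(prof.values, label=tp.label)
            for size in tp.band_sizes:
                truth_rows.append(
                    {
                        "replicate": rep,
                        "condition": tp.label,
                        "band_size_nt": size,
                        "band_centre_index": index_of_size(cal, size),
                        "smear_fraction": tp.smear_fraction,
                        "gaussian_mass": (1.0 - tp.smear_fraction)
                        * gaussian_band_mass(amp, spec.band_sigma),
                        "smear_mass": tp.smear_fraction
                        * gaussian_band_mass(amp, spec.band_sigma),
                    }
                )
        ladder_prof = synth_profile(ladder_spec, cal, spec.lane_length)
        blank_prof = synth_profile(blank_spec, cal, spec.lane_length)
        control_label = spec.timepoints[0].label
        runs.append(
            GelRun(
                gel_id=f"synthetic-gel-{rep}",
                date="",
                ladder=ladder_prof.with_values(ladder_prof.values, label="ladder"),
                background_lanes=[blank_prof.with_values(blank_prof.values, label="blank")],
                control=lanes.pop(control_label),
                samples=lanes,
            )
        )
    return runs, pd.DataFrame(truth_rows)
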