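"""AUC-based degradation scores for single-product and total-RNA lanes.

The headline metric is the preservation score. For a single-product lane
(e.g. IVT mRNA) it combines the two ingredients of degradation — loss of
product-peak signal and growth of the low-molecular-weight smear — as

    P = AUC_peak / (AUC_peak + AUC_degradation),

bounded in (0, 1], equal to 1 for fully preserved product, and normalized
by dividing by the control lane's score. For total RNA the preservation
score is the product of the control-normalized 18S and 28S peak AUCs, and
the combined score additionally folds in each peak's degradation zone:

    combined = prod_k [ P_k / P_k(control) ],   P_k = peak_k / (peak_k + deg_k).

All normalized quantities equal exactly 1 for the control lane. The
single-peak preservation formula can be swapped via the ``strategy``
scoring option, since different labs weight the two ingredients
differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .background import subtract_background
from .calibration import is_extrapolated, mw_at_index, peak_shift_metrics
from .model import (
    BackgroundModel,
    GelRun,
    LadderCalibration,
    LanePartition,
    LaneProfile,
    ScoreRecord,
)
from .zoning import DEFAULT_PEAK_WIDTH, partition_single_peak, partition_two_peaks

__all__ = [
    "ScoringOptions",
    "normalize_to_control",
    "preservation_score_single",
    "preservation_score_total_rna",
    "combined_score",
    "score_run",
]

_EPS = 1e-12  # denominator floor: turns division-by-zero into a clean error


@dataclass(frozen=True)
class ScoringOptions:
    """Tunable parameters of the scoring pipeline.

    mode
        ``"single-peak"`` (one product band, e.g. IVT mRNA) or
        ``"two-peak"`` (total RNA, 18S + 28S).
    background
        Optional background model to subtract before zoning; pass None when
        profiles are already corrected.
    peak_width
        Width of each peak window in indexes (default 20).
    floor_index
        Lower bound of the lowest degradation zone; raise above 0 to exclude
        primer/dye fronts.
    min_separation
        Minimum index separation between the two ribosomal peaks.
    strategy
        Single-peak preservation formula ``f(peak_auc, degradation_auc)``;
        defaults to :func:`preservation_score_single`.
    """

    mode: str = "single-peak"
    background: Optional[BackgroundModel] = None
    peak_width: int = DEFAULT_PEAK_WIDTH
    floor_index: int = 0
    min_separation: int = 20
    strategy: Optional[Callable[[float, float], float]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("single-peak", "two-peak"):
            raise ValueError(f"mode must be 'single-peak' or 'two-peak', got {self.mode!r}")


def normalize_to_control(value: float, control_value: float) -> float:
    """Fold change of a measurement relative to the control lane."""
    if control_value <= _EPS:
        raise ValueError("control lane has no measurable signal")
    return value / control_value


def preservation_score_single(peak_auc: float, degradation_auc: float) -> float:
    """Default single-product preservation score, in (0, 1].

    ``peak / (peak + degradation)``: 1 for pure intact product, decreasing
    as signal mass moves from the peak window into the degradation zone.
    """
    if degradation_auc < 0:
        raise ValueError("degradation AUC must be non-negative")
    if peak_auc <= _EPS and degradation_auc <= _EPS:
        raise ValueError("no signal in either zone; cannot score an empty lane")
    if peak_auc <= _EPS:
        return 0.0
    return peak_auc / (peak_auc + degradation_auc)


def preservation_score_total_rna(peak18_norm: float, peak28_norm: float) -> float:
    """Total-RNA preservation score: product of the two normalized peak AUCs."""
    if peak18_norm <= 0 or peak28_norm <= 0:
        raise ValueError("normalized peak AUCs must be positive")
    return peak18_norm * peak28_norm


def combined_score(
    partition: LanePartition,
    control_partition: LanePartition,
    strategy: Optional[Callable[[float, float], float]] = None,
) -> float:
    """Control-normalized per-peak preservation, multiplied over peaks.

    For each peak k, ``P_k = peak_k / (peak_k + deg_k)`` (or the supplied
    strategy); the combined score is ``prod_k P_k / P_k(control)``. A
    single-peak partition reduces to the normalized preservation score.
    """
    if len(partition.peak_aucs) != len(control_partition.peak_aucs):
        raise ValueError(
            f"peak count mismatch: {len(partition.peak_aucs)} vs control "
            f"{len(control_partition.peak_aucs)}"
        )
    score_fn = strategy or preservation_score_single
    out = 1.0
    for pk, dk, cpk, cdk in zip(
        partition.peak_aucs,
        partition.degradation_aucs,
        control_partition.peak_aucs,
        control_partition.degradation_aucs,
    ):
        p = score_fn(pk, dk)
        p_control = score_fn(cpk, cdk)
        out *= normalize_to_control(p, p_control)
    return out


def _partition(profile: LaneProfile, options: ScoringOptions) -> LanePartition:
    if options.mode == "single-peak":
        return partition_single_peak(profile, options.peak_width, options.floor_index)
    return partition_two_peaks(
        profile, options.min_separation, options.peak_width, options.floor_index
    )


def score_run(
    run: GelRun,
    cal: Optional[LadderCalibration] = None,
    options: Optional[ScoringOptions] = None,
) -> list[ScoreRecord]:
    """Score every sample lane of a gel run against its control.

    Returns one record per lane, control first. Profiles are background
    corrected when ``options.background`` is set; molecular weights and peak
    shifts are populated only in single-peak mode and only when a ladder
    calibration is supplied. Deterministic given its inputs.
    """
    options = options or ScoringOptions()
    if run.control is None:
        raise ValueError("gel run has no control lane; scoring requires a control")
    if run.lane_length < 30:
        raise ValueError(
            f"lane length {run.lane_length} < 30: too short to host a "
            f"{options.peak_width}-index peak window plus a degradation zone"
        )

    lanes: list[tuple[str, LaneProfile]] = [("control", run.control)]
    lanes += list(run.samples.items())

    partitions: dict[str, LanePartition] = {}
    peak_indices: dict[str, int] = {}
    for label, profile in lanes:
        try:
            corrected = (
                subtract_background(profile, options.background)
                if options.background is not None
                else profile
            )
            part = _partition(corrected, options)
        except ValueError as exc:
            raise ValueError(f"lane {label!r}: {exc}") from exc
        partitions[label] = part
        # single-peak: the lane maximum is the centre of the only peak window
        if options.mode == "single-peak":
            peak_indices[label] = part.peak_windows[0].start + int(
                np.argmax(
                    (corrected.values)[part.peak_windows[0].start : part.peak_windows[0].end]
                )
            )

    score_fn = options.strategy or preservation_score_single
    control_part = partitions["control"]
    control_pres = _preservation_raw(control_part, score_fn)

    records: list[ScoreRecord] = []
    for label, _ in lanes:
        part = partitions[label]
        try:
            peak_norm = tuple(
                normalize_to_control(p, cp)
                for p, cp in zip(part.peak_aucs, control_part.peak_aucs)
            )
            deg_norm = tuple(
                (normalize_to_control(d, cd) if cd > _EPS else np.nan)
                for d, cd in zip(part.degradation_aucs, control_part.degradation_aucs)
            )
            pres_raw = _preservation_raw(part, score_fn)
            if options.mode == "single-peak":
                pres_norm = normalize_to_control(pres_raw, control_pres)
            else:
                pres_norm = preservation_score_total_rna(*peak_norm)
            combined = combined_score(part, control_part, options.strategy)
        except ValueError as exc:
            raise ValueError(f"lane {label!r}: {exc}") from exc

        mw = shift = None
        extrapolated = False
        peak_idx = peak_indices.get(label)
        if cal is not None and options.mode == "single-peak":
            mw = mw_at_index(cal, peak_idx)
            extrapolated = is_extrapolated(cal, peak_idx)
            shift = peak_shift_metrics(peak_idx, peak_indices["control"], cal)
        records.append(
            ScoreRecord(
                condition=label,
                peak_aucs=part.peak_aucs,
                degradation_aucs=part.degradation_aucs,
                peak_aucs_norm=peak_norm,
                degradation_aucs_norm=deg_norm,
                preservation_raw=pres_raw,
                preservation_norm=pres_norm,
                combined_norm=combined,
                high_mw_auc=part.high_mw_auc,
                mw_max=mw,
                mw_extrapolated=extrapolated,
                peak_shift=shift,
                peak_index=peak_idx,
            )
        )
    return records


def _preservation_raw(
    part: LanePartition, score_fn: Callable[[float, float], float]
) -> float:
    """Raw preservation: product over peaks of the per-peak score."""
    out = 1.0
    for pk, dk in zip(part.peak_aucs, part.degradation_aucs):
        out *= score_fn(pk, dk)
    return out
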