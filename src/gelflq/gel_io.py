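"""Readers and writers: gel images, plot-profile workbooks, score tables.

Profile workbooks are the spreadsheet exports produced by measuring each
lane of a gel with an image-analysis plot-profile tool, laid out one column
per lane in the conventional order: distance, background (when measured
directly), nucleic-acid ladder, control, then each time point/condition.
Columns are identified by header name when a header row is present, by that
positional order otherwise, and either can be overridden explicitly.

Internally, profiles are always indexed from the gel bottom (index 0 = the
migration front); set ``flip=True`` when the export runs top-to-bottom.
The physical distance column is used only to validate uniform sampling —
all downstream quantities are per index.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .model import GelImage, GelRun, LaneProfile, ScoreRecord

__all__ = [
    "read_gel_image",
    "write_gel_image",
    "read_profile_workbook",
    "write_profile_workbook",
    "write_score_table",
    "read_score_table",
    "SCORE_TABLE_COLUMNS",
]

_ROLE_NAMES = {
    "distance": ("distance", "index", "x"),
    "background": ("background", "blank", "bg"),
    "ladder": ("ladder", "marker", "mw"),
    "control": ("control", "ctrl", "c0"),
}


def read_gel_image(path, invert: bool = False, bottom_edge: str = "bottom") -> GelImage:
    """Read an 8/16-bit grayscale TIFF or PNG gel image.

    ``invert=True`` maps every value v to ``max - v``, turning a
    light-background scan into the light-bands-on-dark convention the
    pipeline assumes. Color images are accepted only when all channels are
    identical (a grayscale image saved as RGB); otherwise an error names
    the offending property.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3:
        if pixels.shape[2] in (3, 4) and all(
            np.array_equal(pixels[..., 0], pixels[..., k]) for k in range(1, 3)
        ):
            pixels = pixels[..., 0]
        else:
            raise ValueError(
                f"{path.name}: multi-channel color image with distinct channels; "
                "convert to grayscale first"
            )
    if pixels.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D grayscale image, got shape {pixels.shape}")
    if pixels.dtype == np.uint8:
        bit_depth = 8
    elif pixels.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path.name}: unsupported pixel dtype {pixels.dtype}; expected uint8/uint16")
    if invert:
        pixels = (2**bit_depth - 1) - pixels
    return GelImage(pixels=pixels, bit_depth=bit_depth, bottom_edge=bottom_edge)


def write_gel_image(image: GelImage, path) -> None:
    """Write a GelImage as TIFF or PNG (dtype follows the bit depth)."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), image.pixels.astype(dtype))


def _load_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path, sheet_name=0, header=None, dtype=object, engine="openpyxl")
    return pd.read_csv(path, header=None, dtype=object, skip_blank_lines=False)


def _is_number(cell) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return False
    try:
        float(cell)
        return True
    except (TypeError, ValueError):
        return False


def read_profile_workbook(
    path,
    column_order: Optional[Sequence[str]] = None,
    flip: bool = False,
    gel_id: Optional[str] = None,
    date: str = "",
) -> GelRun:
    """Parse a plot-profile workbook (XLSX first sheet, or CSV) into a GelRun.

    ``column_order`` overrides column identification: one label per profile
    column (excluding the mandatory first distance column unless named),
    using the role tokens ``distance``, ``background``, ``ladder``,
    ``control``; anything else becomes a sample label. ``flip=True``
    reverses every profile (for exports running top-to-bottom).
    """
    path = Path(path)
    raw = _load_table(path)
    # drop trailing all-empty rows and columns
    raw = raw.dropna(axis=0, how="all").dropna(axis=1, how="all")
    if raw.shape[1] < 3:
        raise ValueError(
            f"{path.name}: need a distance column plus >= 2 profile columns, got {raw.shape[1]}"
        )

    first_row = raw.iloc[0].tolist()
    has_header = any(not _is_number(c) for c in first_row if c is not None)
    if has_header:
        headers = [str(c).strip() if c is not None else "" for c in first_row]
        body = raw.iloc[1:].reset_index(drop=True)
        header_offset = 1
    else:
        headers = [""] * raw.shape[1]
        body = raw.reset_index(drop=True)
        header_offset = 0

    # parse all cells to floats with coordinates on failure
    data = np.empty(body.shape, dtype=float)
    for j in range(body.shape[1]):
        col = body.iloc[:, j].tolist()
        for i, cell in enumerate(col):
            if not _is_number(cell):
                raise ValueError(
                    f"{path.name}: non-numeric cell {cell!r} at row {i + 1 + header_offset}, "
                    f"column {j + 1}"
                )
            data[i, j] = float(cell)

    n_cols = data.shape[1]
    roles = _assign_roles(headers, n_cols, column_order, path.name)
    labels_by_col = (
        [str(label).strip() for label in column_order] if column_order is not None else headers
    )

    # distance column: retained only to validate uniform spacing
    dist_j = roles.index("distance")
    distance = data[:, dist_j]
    steps = np.diff(distance)
    if steps.size and (steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9)):
        raise ValueError(
            f"{path.name}: distance column is not uniformly spaced; "
            "mixed-unit or resampled exports are rejected"
        )

    ladder = control = None
    background: list[LaneProfile] = []
    samples: dict[str, LaneProfile] = {}
    for j, role in enumerate(roles):
        if role == "distance":
            continue
        values = data[:, j]
        if flip:
            values = values[::-1]
        label = labels_by_col[j] if labels_by_col[j] else role
        profile = LaneProfile(label=label, values=values, source="workbook-column")
        if role == "ladder":
            if ladder is not None:
                raise ValueError(f"{path.name}: more than one ladder column")
            ladder = profile
        elif role == "control":
            if control is not None:
                raise ValueError(f"{path.name}: more than one control column")
            control = profile
        elif role == "background":
            background.append(profile)
        else:  # sample
            key = label if label not in samples else f"{label}_{j}"
            samples[key] = profile
    return GelRun(
        gel_id=gel_id if gel_id is not None else path.stem,
        date=date,
        ladder=ladder,
        background_lanes=background,
        control=control,
        samples=samples,
    )


def _assign_roles(
    headers: list[str], n_cols: int, column_order: Optional[Sequence[str]], name: str
) -> list[str]:
    """Role per column: explicit order > header names > protocol position."""
    if column_order is not None:
        if len(column_order) != n_cols:
            raise ValueError(
                f"{name}: column_order has {len(column_order)} labels for {n_cols} columns"
            )
        return [_role_of(label) for label in column_order]
    if any(headers):
        return [_role_of(h) for h in headers]
    # headerless: the conventional positional order
    roles = ["distance", "background", "ladder", "control"]
    if n_cols < 4:
        roles = ["distance", "ladder", "control"][:n_cols]
    roles = roles[:n_cols]
    roles += ["sample"] * (n_cols - len(roles))
    return roles


def _role_of(label: str) -> str:
    low = str(label).strip().lower()
    for role, aliases in _ROLE_NAMES.items():
        if low in aliases or low.startswith(role):
            return role
    return "sample"


def write_profile_workbook(run: GelRun, path) -> None:
    """Write a GelRun back to CSV/XLSX in the conventional column order."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"distance": np.arange(run.lane_length, dtype=float)}
    for i, bg in enumerate(run.background_lanes):
        cols["background" if i == 0 else f"background_{i}"] = bg.values
    if run.ladder is not None:
        cols["ladder"] = run.ladder.values
    if run.control is not None:
        cols["control"] = run.control.values
    for label, prof in run.samples.items():
        cols[label] = prof.values
    frame = pd.DataFrame(cols)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        frame.to_excel(path, index=False, engine="openpyxl")
    else:
        frame.to_csv(path, index=False)


#: Fixed score-table header (two peak slots; single-peak rows leave slot 2 empty).
SCORE_TABLE_COLUMNS = [
    "condition",
    "n_peaks",
    "peak_auc_1",
    "peak_auc_2",
    "degradation_auc_1",
    "degradation_auc_2",
    "peak_auc_norm_1",
    "peak_auc_norm_2",
    "degradation_auc_norm_1",
    "degradation_auc_norm_2",
    "preservation_raw",
    "preservation_norm",
    "combined_norm",
    "high_mw_auc",
    "mw_max_nt",
    "mw_extrapolated",
    "peak_index",
    "peak_shift_nt",
    "peak_shift_ratio",
]


def write_score_table(records: Sequence[ScoreRecord], path) -> None:
    """Write per-lane scores as a tidy CSV (full float precision)."""
    if not records:
        raise ValueError("no score records to write")
    rows = []
    for r in records:
        def slot(tup, k):
            return tup[k] if k < len(tup) else None

        rows.append(
            {
                "condition": r.condition,
                "n_peaks": len(r.peak_aucs),
                "peak_auc_1": slot(r.peak_aucs, 0),
                "peak_auc_2": slot(r.peak_aucs, 1),
                "degradation_auc_1": slot(r.degradation_aucs, 0),
                "degradation_auc_2": slot(r.degradation_aucs, 1),
                "peak_auc_norm_1": slot(r.peak_aucs_norm, 0),
                "peak_auc_norm_2": slot(r.peak_aucs_norm, 1),
                "degradation_auc_norm_1": slot(r.degradation_aucs_norm, 0),
                "degradation_auc_norm_2": slot(r.degradation_aucs_norm, 1),
                "preservation_raw": r.preservation_raw,
                "preservation_norm": r.preservation_norm,
                "combined_norm": r.combined_norm,
                "high_mw_auc": r.high_mw_auc,
                "mw_max_nt": r.mw_max,
                "mw_extrapolated": r.mw_extrapolated,
                "peak_index": r.peak_index,
                "peak_shift_nt": r.peak_shift.shift if r.peak_shift else None,
                "peak_shift_ratio": r.peak_shift.ratio if r.peak_shift else None,
            }
        )
    pd.DataFrame(rows, columns=SCORE_TABLE_COLUMNS).to_csv(Path(path), index=False)


def read_score_table(path) -> pd.DataFrame:
    """Read a score table written by :func:`write_score_table`."""
    frame = pd.read_csv(Path(path), float_precision="round_trip")
    missing = set(SCORE_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing score-table columns {sorted(missing)}")
    return frame
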