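"""Whole-lane intensity profiles from gel images.

Reproduces the rectangle-box + plot-profile procedure of image analysis
software: a fixed box is drawn over each lane and, for every position along
the direction of migration, the mean gray value across the box's short axis
is recorded. All lanes of one gel must be measured with an identical box so
their profiles are comparable index by index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GelImage, GelRun, LaneProfile

__all__ = ["LaneBox", "rotate_quarter", "extract_lane_profile", "extract_run"]

# bottom_edge relabelling under one 90-degree clockwise rotation
_CLOCKWISE = {"bottom": "left", "left": "top", "top": "right", "right": "bottom"}


@dataclass(frozen=True)
class LaneBox:
    """Rectangular measurement box in pixel coordinates.

    ``origin_row``/``origin_col`` locate the top-left corner (0-based);
    extents are half-open, so the box covers rows
    ``[origin_row, origin_row + height)`` and columns
    ``[origin_col, origin_col + width)``. ``long_axis`` is the direction of
    migration: ``"rows"`` when lanes run vertically in the image, ``"cols"``
    when they run horizontally. Only whole-pixel boxes are accepted.
    """

    origin_row: int
    origin_col: int
    height: int
    width: int
    long_axis: str = "rows"

    def __post_init__(self) -> None:
        for name in ("origin_row", "origin_col", "height", "width"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise ValueError(f"{name} must be a whole number of pixels, got {v!r}")
        if self.height < 1 or self.width < 1:
            raise ValueError("box height and width must be >= 1 pixel")
        if self.origin_row < 0 or self.origin_col < 0:
            raise ValueError("box origin must be non-negative")
        if self.long_axis not in ("rows", "cols"):
            raise ValueError(f"long_axis must be 'rows' or 'cols', got {self.long_axis!r}")

    def check_within(self, image: GelImage) -> None:
        rows, cols = image.shape
        if self.origin_row + self.height > rows or self.origin_col + self.width > cols:
            raise ValueError(
                f"box rows [{self.origin_row}, {self.origin_row + self.height}) x "
                f"cols [{self.origin_col}, {self.origin_col + self.width}) exceeds "
                f"image of shape {rows}x{cols}"
            )


def rotate_quarter(image: GelImage, turns: int) -> GelImage:
    """Rotate the image by ``turns`` x 90 degrees clockwise.

    ``turns`` is normalized modulo 4; the ``bottom_edge`` metadata is
    relabelled consistently so the gel bottom keeps pointing at the same
    physical edge.
    """
    turns = int(turns) % 4
    pixels = np.rot90(image.pixels, k=-turns)
    edge = image.bottom_edge
    for _ in range(turns):
        edge = _CLOCKWISE[edge]
    return GelImage(pixels=pixels, bit_depth=image.bit_depth, bottom_edge=edge)


def extract_lane_profile(image: GelImage, box: LaneBox, label: str) -> LaneProfile:
    """Mean-intensity profile of one lane, re-oriented bottom-first.

    For each position along the box's long axis the profile value is the
    arithmetic mean of the pixels across the short axis. The result is
    flipped if needed so that index 0 corresponds to the image edge named by
    ``image.bottom_edge`` (the migration front).
    """
    box.check_within(image)
    region = image.pixels[
        box.origin_row : box.origin_row + box.height,
        box.origin_col : box.origin_col + box.width,
    ].astype(float)
    if box.long_axis == "rows":
        if image.bottom_edge not in ("top", "bottom"):
            raise ValueError(
                f"box long_axis 'rows' is inconsistent with bottom_edge "
                f"{image.bottom_edge!r}: migration must run toward the gel bottom"
            )
        values = region.mean(axis=1)
        if image.bottom_edge == "bottom":
            values = values[::-1]
    else:
        if image.bottom_edge not in ("left", "right"):
            raise ValueError(
                f"box long_axis 'cols' is inconsistent with bottom_edge "
                f"{image.bottom_edge!r}: migration must run toward the gel bottom"
            )
        values = region.mean(axis=0)
        if image.bottom_edge == "right":
            values = values[::-1]
    return LaneProfile(label=label, values=values, source="image-box")


def extract_run(
    image: GelImage,
    boxes: list[LaneBox],
    labels: list[str],
    roles: list[str],
    gel_id: str = "",
    date: str = "",
) -> GelRun:
    """Measure a set of lanes with identical boxes and assemble a GelRun.

    ``roles`` tags each box as ``"ladder"``, ``"background"``, ``"control"``
    or ``"sample"``. Exactly one ladder and at most one control are allowed;
    background boxes are optional (the background can still be computed from
    a reference lane downstream).
    """
    if not (len(boxes) == len(labels) == len(roles)):
        raise ValueError("boxes, labels and roles must have equal length")
    if not boxes:
        raise ValueError("at least one box is required")
    dims = {(b.height, b.width, b.long_axis) for b in boxes}
    if len(dims) != 1:
        raise ValueError("lanes must be measured with an identical box (equal height/width/axis)")
    valid_roles = {"ladder", "background", "control", "sample"}
    bad = set(roles) - valid_roles
    if bad:
        raise ValueError(f"unknown roles {sorted(bad)}; expected one of {sorted(valid_roles)}")
    if roles.count("ladder") != 1:
        raise ValueError("exactly one box must be tagged 'ladder'")
    if roles.count("control") > 1:
        raise ValueError("at most one box may be tagged 'control'")

    ladder = None
    control = None
    background: list[LaneProfile] = []
    samples: dict[str, LaneProfile] = {}
    for box, label, role in zip(boxes, labels, roles):
        profile = extract_lane_profile(image, box, label)
        if role == "ladder":
            ladder = profile
        elif role == "control":
            control = profile
        elif role == "background":
            background.append(profile)
        else:
            if label in samples:
                raise ValueError(f"duplicate sample label {label!r}")
            samples[label] = profile
    return GelRun(
        gel_id=gel_id,
        date=date,
        ladder=ladder,
        background_lanes=background,
        control=control,
        samples=samples,
    )
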