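"""Per-cell geometric features, quadrant splitting and edge-cell removal.

Each labeled object is measured for area, perimeter, major/minor axis
length (moment-equivalent ellipse), aspect ratio (major/minor, always
>= 1) and circularity 4π·A/P².  Circularity is 1 for a continuum circle
and decreases with branching; note that because the perimeter of a
rasterized shape is an estimate, circularity of small compact pixelated
objects can slightly exceed 1.

The perimeter estimator is a corner-corrected weighted boundary-step
estimator: the 8-connected boundary chain code is traced (Moore
neighborhood) and its length taken as 0.980·(orthogonal steps) +
1.406·(diagonal steps) − 0.091·(corners), the Vossepoel–Smeulders
weights, plus a π offset accounting for the half-pixel band between
pixel centers and the true object boundary.  This keeps both disks and
axis-aligned rectangles within a few percent of their continuum
perimeter, which the plain unit/√2 step weights do not.  The estimator
name is recorded in output metadata because circularity depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from gliamorph.segmentation import LabeledMask

PERIMETER_ESTIMATOR = "chain-code-vossepoel-smeulders+pi"

#: clockwise 8-neighborhood moves starting north
_MOVES = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


class ParameterError(ValueError):
    pass


@dataclass
class CellRecord:
    """Geometry of one segmented object."""

    image_id: str
    label: int
    quadrant: str  # "whole" or "1".."4"
    area_px: int
    area_um2: float
    perimeter_px: float
    major_axis_px: float
    minor_axis_px: float
    aspect_ratio: float
    circularity: float
    centroid: tuple[float, float]
    touches_edge: bool
    degenerate: bool = False
    shape_mode: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["centroid_row"], d["centroid_col"] = d.pop("centroid")
        return d


def circularity(area: float, perimeter: float) -> float:
    """4π·area/perimeter² — 1 for a circle, π/4 for a square."""
    if area <= 0 or perimeter <= 0:
        raise ParameterError("area and perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def _boundary_chain_code(mask: np.ndarray) -> list[int]:
    """8-connected clockwise boundary chain code (Moore tracing).

    Starts at the topmost-leftmost pixel and stops when the tracing
    state (pixel, backtrack direction) repeats, which closes the full
    boundary cycle even on objects with one-pixel-wide spurs.  Returns
    an empty list for an isolated pixel.
    """
    mask = np.pad(np.asarray(mask, dtype=bool), 1)
    rows, cols = np.nonzero(mask)
    cur = (int(rows[0]), int(cols[0]))
    b = 6  # enter searching from the west
    codes: list[int] = []
    seen: dict[tuple, int] = {}
    while True:
        state = (cur, b)
        if state in seen:
            return codes[seen[state]:]
        seen[state] = len(codes)
        for i in range(8):
            d = (b + 1 + i) % 8
            nr, nc = cur[0] + _MOVES[d][0], cur[1] + _MOVES[d][1]
            if mask[nr, nc]:
                codes.append(d)
                cur = (nr, nc)
                b = (d + 4) % 8
                break
        else:
            return []  # isolated pixel: no neighbors


def perimeter_estimate(obj_mask: np.ndarray) -> float:
    """Boundary length of a single binary object in pixels.

    Corner-corrected chain-code estimator (see module docstring).  A
    single isolated pixel has no chain steps and yields the bare π
    offset ≈ 3.14 — close to the outline of its half-pixel band — and
    is in any case flagged degenerate upstream.
    """
    obj_mask = np.asarray(obj_mask).astype(bool)
    if not obj_mask.any():
        raise ParameterError("empty object has no perimeter")
    codes = np.asarray(_boundary_chain_code(obj_mask))
    if codes.size == 0:
        return float(np.pi)
    n_diag = int((codes % 2 == 1).sum())
    n_orth = int(codes.size - n_diag)
    n_corner = int((codes != np.roll(codes, 1)).sum())
    return 0.980 * n_orth + 1.406 * n_diag - 0.091 * n_corner + float(np.pi)


def axis_lengths(obj_mask: np.ndarray) -> tuple[float, float]:
    """(major, minor) axis lengths of the moment-equivalent ellipse."""
    obj_mask = np.asarray(obj_mask).astype(bool)
    props = regionprops(obj_mask.astype(np.uint8))
    if not props:
        raise ParameterError("empty object")
    p = props[0]
    major, minor = p.axis_major_length, p.axis_minor_length
    if minor == 0:
        raise ParameterError("degenerate (collinear) object")
    return float(major), float(minor)


def extract_cells(mask: LabeledMask | np.ndarray, pixel_size_um: float = 1.0,
                  image_id: str = "", quadrant: str = "whole") -> list[CellRecord]:
    """Measure every labeled object in a mask.

    ``touches_edge`` is true iff any pixel of the object lies on the
    outer boundary row/column of the array the object was measured in.
    Objects of fewer than 3 pixels or with a zero minor axis are flagged
    degenerate (excluded from shape-mode fitting, kept in QC counts).
    """
    labels = mask.labels if isinstance(mask, LabeledMask) else np.asarray(mask)
    h, w = labels.shape
    records: list[CellRecord] = []
    for p in regionprops(labels):
        minr, minc, maxr, maxc = p.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        area = int(p.area)
        degenerate = area < 3 or p.axis_minor_length == 0
        if degenerate:
            perim = perimeter_estimate(p.image)
            records.append(CellRecord(
                image_id, int(p.label), quadrant, area,
                area * pixel_size_um**2, perim, float(p.axis_major_length),
                float(p.axis_minor_length), np.nan, np.nan,
                (float(p.centroid[0]), float(p.centroid[1])), touches,
                degenerate=True))
            continue
        perim = perimeter_estimate(p.image)
        major = float(p.axis_major_length)
        minor = float(p.axis_minor_length)
        records.append(CellRecord(
            image_id, int(p.label), quadrant, area, area * pixel_size_um**2,
            perim, major, minor, major / minor,
            circularity(area, perim),
            (float(p.centroid[0]), float(p.centroid[1])), touches))
    return records


def quadrant_slices(shape: tuple[int, int]) -> list[tuple[slice, slice]]:
    """Slices of the four equal quadrants (NW, NE, SW, SE).

    Odd dimensions split as ceil/floor, so tile sizes differ by at most
    one pixel per dimension and the tiles partition the array exactly.
    """
    h, w = shape
    if h < 2 or w < 2:
        raise ParameterError("both dimensions must be >= 2 to split")
    rh, cw = (h + 1) // 2, (w + 1) // 2
    return [(slice(0, rh), slice(0, cw)), (slice(0, rh), slice(cw, w)),
            (slice(rh, h), slice(0, cw)), (slice(rh, h), slice(cw, w))]


def split_quadrants(array: np.ndarray) -> list[np.ndarray]:
    """Split an image or mask into four equal quadrant tiles."""
    array = np.asarray(array)
    return [array[rs, cs] for rs, cs in quadrant_slices(array.shape[:2])]


def remove_edge_touching(cells: list[CellRecord]) -> list[CellRecord]:
    """Drop every record whose object touches its tile's edge."""
    return [c for c in cells if not c.touches_edge]


def measure_quadrants(mask: LabeledMask | np.ndarray, pixel_size_um: float = 1.0,
                      image_id: str = "",
                      drop_edge: bool = True) -> list[CellRecord]:
    """Quadrant-wise measurement with per-tile edge removal.

    The mask is split into four equal quadrants; objects are relabeled and
    measured inside each tile, and (by default) any object touching a tile
    edge — including the artificial edges created by the split — is
    removed.  An object spanning a quadrant boundary therefore disappears
    from both adjacent quadrants.
    """
    from skimage.measure import label as _label

    labels = mask.labels if isinstance(mask, LabeledMask) else np.asarray(mask)
    conn = mask.connectivity if isinstance(mask, LabeledMask) else 8
    out: list[CellRecord] = []
    for q, tile in enumerate(split_quadrants(labels), start=1):
        relabeled = _label(tile > 0, connectivity=2 if conn == 8 else 1)
        cells = extract_cells(relabeled, pixel_size_um, image_id, quadrant=str(q))
        if drop_edge:
            cells = remove_edge_touching(cells)
        out.extend(cells)
    return out


def records_to_dataframe(cells: list[CellRecord]) -> pd.DataFrame:
    """One row per cell; empty input yields an empty frame with columns."""
    cols = ["image_id", "label", "quadrant", "area_px", "area_um2",
            "perimeter_px", "major_axis_px", "minor_axis_px", "aspect_ratio",
            "circularity", "touches_edge", "degenerate", "shape_mode",
            "centroid_row", "centroid_col"]
    if not cells:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([c.to_dict() for c in cells])[cols]
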