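"""Threshold survey, Li binarization and mask cleanup.

Segmentation of Iba-1-stained fields proceeds in three steps: a survey of
seven histogram-based thresholds (isodata, li, mean, minimum, otsu,
triangle, yen) for qualitative comparison, binarization at the Li
minimum-cross-entropy threshold (foreground = bright), and cleanup —
removal of objects strictly smaller than a physically derived pixel-area
cutoff followed by hole filling — yielding a labeled mask.

The default cutoff of 71 px² reproduces the applied pipeline constant.
The stated derivation (half the 1600 μm² average microglial area at
3.4527 μm/px) gives 67.11 px²; both are exposed —
:func:`min_area_from_physical` computes the derivation, while the applied
constant lives in :class:`SegmentationConfig`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as _filters
from skimage.measure import label as _label


class DegenerateImageError(ValueError):
    """Image has too little intensity variation to threshold."""


class ParameterError(ValueError):
    pass


def _threshold_minimum(image: np.ndarray) -> float:
    """Minimum-method threshold, robust to peaks at the intensity extremes.

    The histogram walk used by the minimum method only records a maximum
    when the count descends after it, so a mode sitting exactly at the
    lowest or highest occupied gray level is missed (e.g. a two-value
    image).  Padding the histogram with one empty bin on each side makes
    terminal modes detectable without changing the criterion.
    """
    try:
        return float(_filters.threshold_minimum(image))
    except RuntimeError:
        pass
    flat = np.asarray(image)
    if np.issubdtype(flat.dtype, np.integer):
        lo, hi = int(flat.min()), int(flat.max())
        counts = np.bincount((flat - lo).ravel(), minlength=hi - lo + 1)
        centers = np.arange(lo, hi + 1).astype(float)
    else:
        counts, edges = np.histogram(flat.ravel(), bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
    step = centers[1] - centers[0] if len(centers) > 1 else 1.0
    # two guard bins: the smoothed plateau must descend before the end
    h = np.concatenate([[0, 0], counts, [0, 0]]).astype(np.float32)
    centers = np.concatenate([centers[0] - step * np.array([2.0, 1.0]),
                              centers,
                              centers[-1] + step * np.array([1.0, 2.0])])

    def turning_maxima(hist):
        maxima, direction = [], 1
        for i in range(len(hist) - 1):
            if direction > 0:
                if hist[i + 1] < hist[i]:
                    direction = -1
                    maxima.append(i)
            elif hist[i + 1] > hist[i]:
                direction = 1
        return maxima

    for _ in range(10000):
        h = ndi.uniform_filter1d(h, 3)
        maxima = turning_maxima(h)
        if len(maxima) < 3:
            break
    if len(maxima) != 2:
        raise DegenerateImageError(
            "minimum method: histogram never became bimodal")
    a, b = maxima
    return float(centers[a + int(np.argmin(h[a: b + 1]))])


THRESHOLD_FUNCS: dict[str, Callable] = {
    "isodata": _filters.threshold_isodata,
    "li": _filters.threshold_li,
    "mean": _filters.threshold_mean,
    "minimum": _threshold_minimum,
    "otsu": _filters.threshold_otsu,
    "triangle": _filters.threshold_triangle,
    "yen": _filters.threshold_yen,
}


@dataclass
class ThresholdReport:
    """Thresholds and binary masks from the seven-method survey."""

    thresholds: dict[str, float]
    masks: dict[str, np.ndarray]
    panel_path: str | None = None


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the segmentation stage.

    ``min_object_area_px`` is the applied cutoff (objects *strictly*
    smaller are removed); ``avg_cell_area_um2``/``pixel_size_um``/
    ``area_fraction`` document its physical derivation.  Labeling uses
    8-connectivity by default so thin diagonal processes stay attached to
    their soma.
    """

    method: str = "li"
    min_object_area_px: float = 71.0
    fill_holes: bool = True
    connectivity: int = 8
    avg_cell_area_um2: float = 1600.0
    pixel_size_um: float = 3.4527
    area_fraction: float = 0.5

    def __post_init__(self):
        if self.method not in THRESHOLD_FUNCS:
            raise ParameterError(f"unknown threshold method {self.method!r}; "
                                 f"choose from {sorted(THRESHOLD_FUNCS)}")
        if self.min_object_area_px <= 0:
            raise ParameterError("min_object_area_px must be positive")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if not (0 < self.area_fraction <= 1):
            raise ParameterError("area_fraction must be in (0, 1]")


@dataclass
class LabeledMask:
    """Integer-labeled segmentation; 0 is background, labels contiguous."""

    labels: np.ndarray
    connectivity: int = 8
    provenance: dict = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def binary(self) -> np.ndarray:
        return self.labels > 0

    def areas(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels[self.labels > 0],
                                 return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ParameterError("expected a 2D grayscale image")
    if np.unique(image).size < 2:
        raise DegenerateImageError("constant image cannot be thresholded")
    return image


def _ge_cut(image: np.ndarray, t: float) -> float:
    """Express a threshold as a cut point for the ``image >= t`` rule.

    The underlying criteria define foreground as ``image > t``.  When the
    optimizer lands exactly on an occupied gray level of an integer image
    the two rules differ for that whole level, so the cut is nudged up by
    half a gray step; otherwise no pixel equals ``t`` and the rules agree.
    """
    t = float(t)
    if (np.issubdtype(image.dtype, np.integer) and t.is_integer()
            and bool((image == int(t)).any())):
        return t + 0.5
    return t


def threshold_survey(image: np.ndarray) -> ThresholdReport:
    """Apply all seven thresholding methods to one image.

    Foreground is bright (fluorescence convention): each binary mask is
    ``image >= threshold`` (see :func:`_ge_cut` for the cut convention).
    """
    image = _check_image(image)
    thresholds: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    for name, func in THRESHOLD_FUNCS.items():
        t = _ge_cut(image, func(image))
        thresholds[name] = t
        masks[name] = image >= t
    return ThresholdReport(thresholds, masks)


def li_threshold(image: np.ndarray, tolerance: float = 0.5) -> float:
    """Minimum-cross-entropy (Li & Lee) threshold.

    The iterative fixed-point scheme stops when successive iterates differ
    by less than ``tolerance`` intensity units.
    """
    image = _check_image(image)
    return float(_filters.threshold_li(image, tolerance=tolerance))


def min_area_from_physical(avg_cell_area_um2: float, pixel_size_um: float,
                           area_fraction: float = 0.5) -> float:
    """Pixel-area cutoff from an average physical cell area.

    ``area_fraction * avg_cell_area_um2 / pixel_size_um**2`` — half the
    average cell area by default, so genuine cells are never discarded.
    """
    if avg_cell_area_um2 <= 0 or pixel_size_um <= 0 or area_fraction <= 0:
        raise ParameterError("all physical-cutoff inputs must be positive")
    return area_fraction * avg_cell_area_um2 / pixel_size_um**2


def clean_mask(binary: np.ndarray, config: SegmentationConfig | None = None,
               source: str = "") -> LabeledMask:
    """Remove small objects, fill holes, label.

    Objects *strictly* smaller than ``min_object_area_px`` are removed
    (an object of exactly the cutoff area survives).  Interior holes are
    filled afterwards, then components are labeled 1..n in raster order.
    """
    config = config or SegmentationConfig()
    binary = np.asarray(binary).astype(bool)
    conn = 2 if config.connectivity == 8 else 1
    lab = _label(binary, connectivity=conn)
    counts = np.bincount(lab.ravel())
    keep = counts >= config.min_object_area_px  # strict "smaller than"
    keep[0] = False
    cleaned = keep[lab]
    if config.fill_holes:
        cleaned = ndi.binary_fill_holes(cleaned)
    labels = _label(cleaned, connectivity=conn).astype(np.int32)
    prov = {"source": source, "config_hash": config_hash(config)}
    return LabeledMask(labels, config.connectivity, prov)


def config_hash(config: SegmentationConfig) -> str:
    text = repr(sorted(config.__dict__.items()))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def segment(image: np.ndarray, config: SegmentationConfig | None = None,
            source: str = "") -> LabeledMask:
    """Threshold (configured method, default Li) + cleanup, composed."""
    config = config or SegmentationConfig()
    image = _check_image(image)
    t = _ge_cut(image, THRESHOLD_FUNCS[config.method](image))
    mask = clean_mask(image >= t, config, source=source)
    mask.provenance["threshold"] = t
    mask.provenance["method"] = config.method
    return mask
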