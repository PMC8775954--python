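"""Synthetic Iba-1-like fluorescence images with per-cell ground truth.

Microglia in cortical confocal fields span a morphological continuum from
amoeboid (round, swollen, inflammation-associated) to ramified (small soma
with several thin processes, surveillance-associated).  This module renders
caricatures of that continuum — bright cells on a dark background with
known class labels, positions and pixel areas — so that segmentation,
morphometry and shape-mode clustering can all be validated against ground
truth without access to the original micrographs.

The rendering model is deliberately minimal: binary shape, 1-px Gaussian
edge blur, additive Gaussian read noise and optional Poisson shot noise.
That is enough texture to exercise every histogram-based threshold while
keeping the true mask exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import disk as draw_disk


class ParameterError(ValueError):
    """A shape-class or spec parameter is out of its admissible range."""


class PlacementError(RuntimeError):
    """Could not place all requested cells without overlap."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} cells without overlap; "
            "reduce n_cells, cell size or min_cell_separation_px"
        )


@dataclass(frozen=True)
class ShapeClass:
    """Parameter ranges for one qualitative microglial morphology class.

    Each range is an inclusive ``(low, high)`` pair sampled uniformly per
    cell.  ``elongation`` e stretches the soma into an ellipse with axes
    ``r*sqrt(e)`` and ``r/sqrt(e)`` so the soma area stays close to πr².
    """

    name: str
    soma_radius_px: tuple[float, float]
    n_branches: tuple[int, int]
    branch_length_px: tuple[float, float]
    branch_width_px: tuple[float, float]
    elongation: tuple[float, float] = (1.0, 1.0)
    #: branch-angle jitter as a fraction of the even inter-branch spacing
    #: (< 0.5 keeps branches angularly distinct)
    angle_jitter: float = 0.35

    def __post_init__(self):
        for fname in ("soma_radius_px", "n_branches", "branch_length_px",
                      "branch_width_px", "elongation"):
            lo, hi = getattr(self, fname)
            if hi < lo:
                raise ParameterError(f"{self.name}.{fname}: max {hi} < min {lo}")
        if self.soma_radius_px[0] <= 0:
            raise ParameterError(f"{self.name}: soma radius must be positive")
        if self.elongation[0] < 1:
            raise ParameterError(f"{self.name}: elongation must be >= 1")
        if self.n_branches[0] < 0:
            raise ParameterError(f"{self.name}: branch count must be >= 0")


#: Default class library.  Amoeboid cells are swollen disks; ramified cells
#: have a small soma and several long thin processes; transitional sits in
#: between; elongated and rod are stretched, sparsely branched forms.
DEFAULT_CLASSES: dict[str, ShapeClass] = {
    # swollen, round, inflammation-associated: large soma, no processes
    "amoeboid": ShapeClass("amoeboid", (11.0, 16.0), (0, 0), (0.0, 0.0),
                           (0.0, 0.0), (1.0, 1.3)),
    "transitional": ShapeClass("transitional", (7.0, 10.0), (1, 2),
                               (8.0, 15.0), (2.5, 3.5), (1.0, 1.5)),
    # surveillance-associated: small soma, several long thin processes
    "ramified": ShapeClass("ramified", (4.5, 6.5), (3, 6), (12.0, 25.0),
                           (1.8, 2.4), (1.0, 1.3)),
    "elongated": ShapeClass("elongated", (6.0, 8.0), (0, 2), (10.0, 16.0),
                            (2.0, 3.0), (2.5, 4.0)),
    "rod": ShapeClass("rod", (4.5, 6.0), (0, 1), (12.0, 20.0), (2.0, 3.0),
                      (4.0, 6.0)),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic field of view."""

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 1.0
    n_cells: int = 30
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {"amoeboid": 0.3, "transitional": 0.3,
                                 "ramified": 0.4})
    intensity_fg: float = 0.8
    intensity_bg: float = 0.1
    noise_sd: float = 0.02
    poisson_scale: float = 0.0
    min_cell_separation_px: float = 4.0
    seed: int = 0
    classes: dict[str, ShapeClass] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES))

    def __post_init__(self):
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"class_mixture sums to {total}, not 1")
        if not self.intensity_fg > self.intensity_bg:
            raise ParameterError("intensity_fg must exceed intensity_bg")
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.noise_sd < 0 or self.poisson_scale < 0:
            raise ParameterError("noise parameters must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        unknown = set(self.class_mixture) - set(self.classes)
        if unknown:
            raise ParameterError(f"mixture names not in class library: {unknown}")


@dataclass
class GroundTruth:
    """True segmentation of a synthetic image.

    ``label_mask`` is the rendered (pre-noise) labeling; ``cell_classes``
    and ``cell_areas_px`` are keyed by the same positive labels.
    """

    label_mask: np.ndarray
    cell_classes: dict[int, str]
    cell_areas_px: dict[int, int]


def _sample(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo) if hi == lo else float(rng.uniform(lo, hi))


def generate_cell_shape(cls: ShapeClass, rng: np.random.Generator) -> np.ndarray:
    """Render one cell of class ``cls`` as a binary mask on a tight canvas.

    The soma is an ellipse of equivalent radius ``soma_radius_px`` and
    elongation ``elongation``, at a random orientation.  Branches are
    straight thick rays leaving the soma boundary at angles that are
    jittered but guaranteed angularly separated, so a cell asked for ``n``
    branches really grows ``n`` distinct processes.  The result is a single
    8-connected component.
    """
    r = _sample(rng, *cls.soma_radius_px)
    elong = _sample(rng, *cls.elongation)
    n_br = int(rng.integers(cls.n_branches[0], cls.n_branches[1] + 1))
    a = r * np.sqrt(elong)   # semi-major
    b = r / np.sqrt(elong)   # semi-minor
    max_len = cls.branch_length_px[1] if n_br > 0 else 0.0
    half = int(np.ceil(a + max_len + cls.branch_width_px[1] + 3))
    size = 2 * half + 1
    canvas = np.zeros((size, size), dtype=bool)
    c = half
    theta = rng.uniform(0, 2 * np.pi)
    rr, cc = draw_ellipse(c, c, b, a, shape=canvas.shape, rotation=theta)
    canvas[rr, cc] = True

    if n_br > 0:
        base = rng.uniform(0, 2 * np.pi)
        spacing = 2 * np.pi / n_br
        jitter = min(cls.angle_jitter, 0.49)
        angles = base + spacing * np.arange(n_br) + rng.uniform(
            -jitter * spacing, jitter * spacing, size=n_br)
        for ang in angles:
            length = _sample(rng, *cls.branch_length_px)
            width = max(_sample(rng, *cls.branch_width_px), 1.0)
            # boundary point of the rotated ellipse along direction ang
            phi = ang - theta
            rad = (a * b) / np.hypot(b * np.cos(phi), a * np.sin(phi))
            # start slightly inside the soma to guarantee connectivity
            start = rad - 1.0
            # low-curvature ray: constant direction, stamped with disks
            n_steps = max(int(np.ceil(length * 2)), 2)
            ts = np.linspace(start, start + length, n_steps)
            for t in ts:
                pr = c + t * np.sin(ang)
                pc = c + t * np.cos(ang)
                rr, cc = draw_disk((pr, pc), width / 2.0 + 0.5,
                                   shape=canvas.shape)
                canvas[rr, cc] = True

    # keep the largest component in the pathological case of a clipped ray
    lab, n = ndi.label(canvas, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        canvas = lab == (1 + int(np.argmax(sizes)))
    # tight crop with 1-px margin
    rows = np.flatnonzero(canvas.any(axis=1))
    cols = np.flatnonzero(canvas.any(axis=0))
    return np.pad(canvas[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1], 1)


def generate_image(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a full field of view.

    Returns the noisy float image in [0, 1] and the exact ground truth.
    Cells are placed by rejection sampling (100 retries each) so that no
    two cells come within ``min_cell_separation_px`` of each other, which
    keeps the label/ground-truth correspondence a bijection.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    names = sorted(spec.class_mixture)
    probs = np.array([spec.class_mixture[n] for n in names])
    sep = int(np.ceil(spec.min_cell_separation_px))
    classes: dict[int, str] = {}
    areas: dict[int, int] = {}

    for i in range(spec.n_cells):
        cls_name = names[int(rng.choice(len(names), p=probs))]
        shape = generate_cell_shape(spec.classes[cls_name], rng)
        if sep:
            shape = np.pad(shape, sep)  # room for the separation margin
        sh, sw = shape.shape
        if sh >= h or sw >= w:
            raise ParameterError("cell canvas larger than image")
        grown = ndi.binary_dilation(shape, iterations=sep) if sep else shape
        placed = False
        for _ in range(100):
            r0 = int(rng.integers(0, h - sh + 1))
            c0 = int(rng.integers(0, w - sw + 1))
            if not (occupied[r0:r0 + sh, c0:c0 + sw] & grown).any():
                placed = True
                break
        if not placed:
            raise PlacementError(i, spec.n_cells)
        lab = i + 1
        labels[r0:r0 + sh, c0:c0 + sw][shape] = lab
        occupied[r0:r0 + sh, c0:c0 + sw] |= grown
        classes[lab] = cls_name
        areas[lab] = int(shape.sum())

    image = np.where(labels > 0, spec.intensity_fg, spec.intensity_bg)
    image = ndi.gaussian_filter(image, sigma=1.0)
    if spec.poisson_scale > 0:
        image = rng.poisson(image * spec.poisson_scale) / spec.poisson_scale
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return image, GroundTruth(labels, classes, areas)


class DesignError(ValueError):
    """Duplicate or inconsistent rows in a condition-series design."""


def _image_seed(base_seed: int, group: str, exposure_h: float, rep: int) -> int:
    key = f"{group}|{exposure_h}|{rep}".encode()
    return (zlib.crc32(key) ^ (base_seed * 2654435761 & 0x7FFFFFFF)) % (2**31)


def default_study_design(n_images: int = 2) -> list[dict]:
    """Design emulating the study arms: healthy / OGD / BEV at 0–48 h.

    Mixtures encode the reported qualitative trajectory: healthy fields
    stay ramification-dominant; OGD fields become amoeboid-dominant; the
    treated (BEV) arm tracks the injured arm through 24 h and then shifts
    toward ramified/elongated shapes at 48 h.
    """
    mixtures = {
        ("healthy", 0): {"ramified": 0.45, "transitional": 0.30,
                         "amoeboid": 0.15, "elongated": 0.10},
        ("healthy", 4): {"ramified": 0.45, "transitional": 0.30,
                         "amoeboid": 0.15, "elongated": 0.10},
        ("healthy", 24): {"ramified": 0.50, "transitional": 0.30,
                          "amoeboid": 0.10, "elongated": 0.10},
        ("healthy", 48): {"ramified": 0.50, "transitional": 0.30,
                          "amoeboid": 0.10, "elongated": 0.10},
        ("OGD", 0): {"ramified": 0.30, "transitional": 0.30,
                     "amoeboid": 0.30, "elongated": 0.10},
        ("OGD", 4): {"ramified": 0.15, "transitional": 0.25,
                     "amoeboid": 0.50, "elongated": 0.10},
        ("OGD", 24): {"ramified": 0.10, "transitional": 0.20,
                      "amoeboid": 0.60, "elongated": 0.10},
        ("OGD", 48): {"ramified": 0.10, "transitional": 0.20,
                      "amoeboid": 0.60, "elongated": 0.10},
        ("BEV", 0): {"ramified": 0.30, "transitional": 0.30,
                     "amoeboid": 0.30, "elongated": 0.10},
        ("BEV", 4): {"ramified": 0.15, "transitional": 0.25,
                     "amoeboid": 0.50, "elongated": 0.10},
        ("BEV", 24): {"ramified": 0.10, "transitional": 0.25,
                      "amoeboid": 0.55, "elongated": 0.10},
        ("BEV", 48): {"ramified": 0.40, "transitional": 0.15,
                      "amoeboid": 0.10, "elongated": 0.15, "rod": 0.20},
    }
    return [{"group": g, "exposure_h": t, "class_mixture": m,
             "n_images": n_images, "dose_ug": 25.0 if g == "BEV" else 0.0}
            for (g, t), m in mixtures.items()]


def generate_condition_series(
    design: Sequence[dict],
    base_spec: SyntheticSpec,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[dict], pd.DataFrame]:
    """Generate one seeded image per (group, exposure, replicate).

    Each design row needs ``group``, ``exposure_h``, ``class_mixture`` and
    ``n_images`` (optional ``dose_ug``).  Returns a list of records — each
    with the image, ground truth and metadata — and the design table.  With
    ``out_dir`` set, images and label masks are written as TIFF and the
    design table as ``design.csv`` (image intensities scaled to 16 bit).
    """
    seen: set[tuple] = set()
    records: list[dict] = []
    rows: list[dict] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for row in design:
        group, t = row["group"], row["exposure_h"]
        for rep in range(int(row["n_images"])):
            key = (group, t, rep)
            if key in seen:
                raise DesignError(f"duplicate design key {key}")
            seen.add(key)
            img_seed = _image_seed(seed, group, t, rep)
            spec = SyntheticSpec(
                image_shape=base_spec.image_shape,
                pixel_size_um=base_spec.pixel_size_um,
                n_cells=base_spec.n_cells,
                class_mixture=dict(row["class_mixture"]),
                intensity_fg=base_spec.intensity_fg,
                intensity_bg=base_spec.intensity_bg,
                noise_sd=base_spec.noise_sd,
                poisson_scale=base_spec.poisson_scale,
                min_cell_separation_px=base_spec.min_cell_separation_px,
                seed=img_seed,
                classes=base_spec.classes,
            )
            image, truth = generate_image(spec)
            image_id = f"{group}_{t}h_r{rep}"
            rec = {"image_id": image_id, "group": group, "exposure_h": t,
                   "dose_ug": float(row.get("dose_ug", 0.0)),
                   "replicate": rep, "seed": img_seed,
                   "image": image, "truth": truth}
            image_path = ""
            if out is not None:
                image_path = str(out / f"{image_id}.tif")
                tifffile.imwrite(image_path,
                                 (image * 65535).astype(np.uint16))
                tifffile.imwrite(str(out / f"{image_id}_labels.tif"),
                                 truth.label_mask.astype(np.uint16))
                rec["image_path"] = image_path
            rows.append({"image_path": f"{image_id}.tif",
                         "image_id": image_id, "group": group,
                         "dose_ug": float(row.get("dose_ug", 0.0)),
                         "exposure_h": t, "replicate": rep,
                         "seed": img_seed})
            records.append(rec)
    table = pd.DataFrame(rows)
    if out is not None:
        table.to_csv(out / "design.csv", index=False)
    return records, table
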