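"""Population shape-mode analysis of cell contours.

The analysis follows the VAMPIRE family of methods: the closed outer
boundary of every cell is traced at subpixel resolution, resampled to a
fixed number of equally spaced points, registered (translation, scale and
rotation removed, start point and orientation normalized), embedded by
PCA, and clustered with k-means into *k* shape modes — recurring
morphology phenotypes.  A Ward dendrogram over the mode centroids orders
modes by similarity.

The interface mirrors the Model/Results convention of statistical
packages: build a :class:`ShapeModeAnalysis` from contours (or via
:meth:`ShapeModeAnalysis.from_masks`), call :meth:`~ShapeModeAnalysis.fit`
to get a :class:`ShapeModeResults` carrying the fitted
:class:`ShapeModeModel`, per-cell assignments and a ``summary()`` table.
The model fits on a train split (default 80:20, stratified by image) and
assigns every cell, train and test alike.

Registration details: contours are oriented counterclockwise in (x=col,
y=row) coordinates, centered, scaled to unit RMS radius, rotated so the
major principal axis of the point set is horizontal (180° ambiguity
resolved by making the x third moment nonnegative), and re-indexed to
start at the point of maximal x.  Mirror images are *not* identified.
Modes are numbered 1..k by decreasing median cell area so labels are
comparable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _linkage, leaves_list
from skimage.measure import find_contours
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from gliamorph.segmentation import LabeledMask


class ParameterError(ValueError):
    pass


class NotFittedError(RuntimeError):
    pass


# ---------------------------------------------------------------- contours

def extract_contour(obj_mask: np.ndarray) -> np.ndarray:
    """Closed outer boundary of a filled object, as (N, 2) (row, col).

    Traced at the 0.5 iso-level, so coordinates are subpixel.  Interior
    holes are ignored (objects are hole-filled upstream); when several
    loops exist the longest is taken.  Points are ordered
    counterclockwise in (x=col, y=row) coordinates and the duplicate
    closing point is dropped.
    """
    obj_mask = np.asarray(obj_mask).astype(float)
    if obj_mask.sum() < 3:
        raise ParameterError("object too small for contour extraction")
    padded = np.pad(obj_mask, 1)
    loops = find_contours(padded, 0.5)
    if not loops:
        raise ParameterError("no contour found")
    contour = max(loops, key=len) - 1.0  # undo pad offset
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    # one pass of closed moving-average smoothing removes the staircase
    # bias of the marching-squares polygon (raw length overestimates a
    # smooth boundary by ~6%; smoothed, ~2%)
    contour = (np.roll(contour, 1, axis=0) + contour
               + np.roll(contour, -1, axis=0)) / 3.0
    return _orient_ccw(contour)


def _signed_area(contour: np.ndarray) -> float:
    # shoelace in (x=col, y=row); positive = counterclockwise in (x, y)
    x, y = contour[:, 1], contour[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _orient_ccw(contour: np.ndarray) -> np.ndarray:
    return contour if _signed_area(contour) > 0 else contour[::-1]


def contour_area(contour: np.ndarray) -> float:
    """Enclosed area by the shoelace formula."""
    return abs(_signed_area(contour))


def contour_length(contour: np.ndarray) -> float:
    """Total arc length of the closed polygon."""
    diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def resample_contour(contour: np.ndarray, n_points: int = 50) -> np.ndarray:
    """Resample a closed contour to ``n_points`` equally spaced points.

    Linear interpolation at equal arc positions along the input polygon
    does not by itself make the *output* chords equal, so the
    redistribution is iterated to a fixed point; afterwards the spacing
    coefficient of variation is < 1e-8 and the points are stable under
    repeated resampling.
    """
    if n_points < 3:
        raise ParameterError("n_points must be >= 3")
    pts = np.asarray(contour, dtype=float)
    for _ in range(200):
        closed = np.vstack([pts, pts[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total == 0:
            raise ParameterError("zero-length contour")
        targets = np.linspace(0.0, total, n_points, endpoint=False)
        pts = np.column_stack([np.interp(targets, s, closed[:, 0]),
                               np.interp(targets, s, closed[:, 1])])
        seg_out = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
        if seg_out.std() <= 1e-8 * seg_out.mean():
            break
    return pts


def register(contour: np.ndarray) -> np.ndarray:
    """Normalize a resampled contour to a pose-free 2N feature vector.

    Removes translation (centroid to origin), scale (unit RMS radius) and
    rotation (major principal axis horizontal, x-skewness >= 0), fixes the
    start point (maximal x, lowest index on ties) and counterclockwise
    orientation, and returns the flattened ``[x0..xN-1, y0..yN-1]``
    vector in (x=col, y=row) coordinates.
    """
    pts = np.asarray(contour, dtype=float)
    xy = np.column_stack([pts[:, 1], pts[:, 0]])  # (x, y)
    xy = xy - xy.mean(axis=0)
    rms = np.sqrt((xy**2).sum(axis=1).mean())
    if rms == 0:
        raise ParameterError("zero-radius contour cannot be registered")
    xy /= rms
    # principal axis from the 2x2 covariance of the point set
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    angle = np.arctan2(major[1], major[0])
    c, s = np.cos(-angle), np.sin(-angle)
    xy = xy @ np.array([[c, -s], [s, c]]).T
    # resolve the 180-degree ambiguity of the axis deterministically
    skew = float(np.sum(xy[:, 0] ** 3))
    if skew < -1e-9 or (abs(skew) <= 1e-9 and float(np.sum(xy[:, 1] ** 3)) < -1e-9):
        xy = -xy
    # re-enforce counterclockwise orientation (flips reverse it)
    area = 0.5 * float(np.sum(xy[:, 0] * np.roll(xy[:, 1], -1)
                              - np.roll(xy[:, 0], -1) * xy[:, 1]))
    if area < 0:
        xy = xy[::-1]
    start = int(np.argmax(np.round(xy[:, 0] / 1e-9) * 1e-9))
    xy = np.roll(xy, -start, axis=0)
    return np.concatenate([xy[:, 0], xy[:, 1]])


def contour_from_vector(vec: np.ndarray) -> np.ndarray:
    """Inverse of the flattening in :func:`register`: (N, 2) as (x, y)."""
    n = len(vec) // 2
    return np.column_stack([vec[:n], vec[n:]])


def _to_complex(vec: np.ndarray) -> np.ndarray:
    n = len(vec) // 2
    return vec[:n] + 1j * vec[n:]


def _from_complex(z: np.ndarray) -> np.ndarray:
    return np.concatenate([z.real, z.imag])


def align_to_reference(vec: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Best cyclic-shift + rotation alignment of one registered vector.

    Principal-axis registration leaves a residual rotation/start-point
    ambiguity for near-symmetric shapes (an n-armed cell has a degenerate
    principal axis).  This resolves it by full Procrustes alignment: over
    all cyclic reparametrizations, pick the shift and rotation angle
    maximizing the correlation with the reference shape.  Deterministic
    (lowest shift wins ties).
    """
    z = _to_complex(np.asarray(vec, dtype=float))
    r = _to_complex(np.asarray(ref, dtype=float))
    n = len(z)
    # c[s] = <roll(z, -s), r>; rotation by -angle(c) makes it real-positive
    corr = np.array([np.vdot(np.roll(z, -s), r) for s in range(n)])
    best = int(np.argmax(np.abs(corr)))
    phase = corr[best] / abs(corr[best]) if abs(corr[best]) > 0 else 1.0
    return _from_complex(np.roll(z, -best) * phase)


def procrustes_align(vectors: np.ndarray, n_iter: int = 3) -> tuple[np.ndarray,
                                                                    np.ndarray]:
    """Generalized Procrustes alignment of registered contour vectors.

    Aligns every shape to the first, then iteratively to the evolving
    mean shape (renormalized to unit RMS radius each round).  Returns the
    aligned vectors and the final reference mean.
    """
    vectors = np.asarray(vectors, dtype=float)
    # initial reference: mean of the axis-registered vectors (order
    # independent, already crudely aligned by the principal axis)
    ref = vectors.mean(axis=0)
    half = len(ref) // 2
    rms0 = np.sqrt(np.mean(ref[:half] ** 2 + ref[half:] ** 2))
    ref = ref / rms0 if rms0 > 0 else vectors[0]
    aligned = vectors
    for _ in range(n_iter):
        aligned = np.array([align_to_reference(v, ref) for v in aligned])
        mean = aligned.mean(axis=0)
        rms = np.sqrt(np.mean(mean[: len(mean) // 2] ** 2
                              + mean[len(mean) // 2:] ** 2))
        ref = mean / rms if rms > 0 else aligned[0]
    return aligned, ref


# ------------------------------------------------------------------ model

@dataclass
class ShapeModeModel:
    """Fitted registered-contour PCA basis + k-means centroids.

    ``basis`` rows are orthonormal principal directions of the registered
    2N-vectors around ``mean_shape``; ``centroids`` live in the PCA score
    space and are stored in mode order (mode 1 first).  Serializable to
    JSON and re-appliable to new cells.
    """

    n_points: int
    n_components: int
    k: int
    mean_shape: np.ndarray
    alignment_reference: np.ndarray
    basis: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    centroids: np.ndarray
    linkage: np.ndarray
    train_fraction: float
    seed: int

    def transform(self, registered: np.ndarray) -> np.ndarray:
        """Align registered 2N-vectors to the model frame and project."""
        registered = np.atleast_2d(registered)
        aligned = np.array([align_to_reference(v, self.alignment_reference)
                            for v in registered])
        return (aligned - self.mean_shape) @ self.basis.T

    def assign(self, contour: np.ndarray) -> tuple[int, float]:
        """Nearest-centroid shape mode (1-based) for a raw contour."""
        vec = register(resample_contour(contour, self.n_points))
        return self.assign_vector(vec)

    def assign_vector(self, registered: np.ndarray) -> tuple[int, float]:
        scores = self.transform(registered)[0]
        d = np.linalg.norm(self.centroids - scores, axis=1)
        mode = int(np.argmin(d))  # argmin takes the lowest index on ties
        return mode + 1, float(d[mode])

    def mode_shape(self, mode: int) -> np.ndarray:
        """Reconstructed mean contour of one mode, as (N, 2) (x, y)."""
        vec = self.mean_shape + self.centroids[mode - 1] @ self.basis
        return contour_from_vector(vec)

    def dendrogram(self) -> tuple[np.ndarray, list[int]]:
        """Ward linkage over centroids and the deterministic leaf order.

        Leaves are 1-based mode labels.
        """
        if self.k < 2:
            raise ParameterError("dendrogram needs k >= 2")
        return self.linkage, [int(i) + 1 for i in leaves_list(self.linkage)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_points": self.n_points, "n_components": self.n_components,
            "k": self.k, "train_fraction": self.train_fraction,
            "seed": self.seed,
            "mean_shape": self.mean_shape.tolist(),
            "alignment_reference": self.alignment_reference.tolist(),
            "basis": self.basis.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "centroids": self.centroids.tolist(),
            "linkage": self.linkage.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ShapeModeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_points=d["n_points"], n_components=d["n_components"],
            k=d["k"], train_fraction=d["train_fraction"], seed=d["seed"],
            mean_shape=np.array(d["mean_shape"]),
            alignment_reference=np.array(d["alignment_reference"]),
            basis=np.array(d["basis"]),
            explained_variance=np.array(d["explained_variance"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            centroids=np.array(d["centroids"]),
            linkage=np.array(d["linkage"]),
        )


class ShapeModeAnalysis:
    """Shape-mode model specification over a population of cell contours.

    Parameters
    ----------
    contours : list of (N_i, 2) arrays
        Raw closed boundaries (row, col), one per cell.
    cell_ids : optional list of identifiers (default 0..n-1).
    image_ids : optional per-cell image identifiers; the train/test split
        is stratified by image when given.
    areas : optional per-cell areas used to order modes; when omitted the
        shoelace area of each raw contour is used.
    k : number of shape modes (default 5).
    n_points : boundary points per resampled contour (default 50).
    n_components : PCA dimensions; ``None`` selects the smallest number
        explaining >= 90% of registered-shape variance, capped at 20.
    train_fraction : fraction of cells used for fitting (default 0.8).
    """

    def __init__(self, contours, cell_ids=None, image_ids=None, areas=None,
                 k: int = 5, n_points: int = 50, n_components: int | None = None,
                 train_fraction: float = 0.8):
        if k < 1:
            raise ParameterError("k must be >= 1")
        if not (0 < train_fraction <= 1):
            raise ParameterError("train_fraction must be in (0, 1]")
        self.contours = list(contours)
        n = len(self.contours)
        self.cell_ids = list(cell_ids) if cell_ids is not None else list(range(n))
        self.image_ids = list(image_ids) if image_ids is not None else [""] * n
        if areas is not None:
            self.areas = np.asarray(areas, dtype=float)
        else:
            self.areas = np.array([contour_area(np.asarray(c)) for c in
                                   self.contours])
        if not (len(self.cell_ids) == len(self.image_ids) == n == len(self.areas)):
            raise ParameterError("contours, ids and areas must align")
        self.k = k
        self.n_points = n_points
        self.n_components = n_components
        self.train_fraction = train_fraction

    @classmethod
    def from_masks(cls, masks, image_ids=None, **kwargs) -> "ShapeModeAnalysis":
        """Build from labeled masks; one contour per (filled) object.

        ``masks`` is a list of :class:`LabeledMask` or integer arrays.
        Objects too small to trace are skipped.
        """
        contours, ids, imgs, areas = [], [], [], []
        image_ids = image_ids or [str(i) for i in range(len(masks))]
        for img_id, m in zip(image_ids, masks):
            labels = m.labels if isinstance(m, LabeledMask) else np.asarray(m)
            for lab in np.unique(labels[labels > 0]):
                obj = labels == lab
                try:
                    c = extract_contour(obj)
                except ParameterError:
                    continue
                contours.append(c)
                ids.append(f"{img_id}:{int(lab)}")
                imgs.append(img_id)
                areas.append(int(obj.sum()))
        return cls(contours, cell_ids=ids, image_ids=imgs, areas=areas, **kwargs)

    # -------------------------------------------------------------- fitting

    def _split(self, rng: np.random.Generator) -> np.ndarray:
        """Boolean train indicator, stratified by image id."""
        n = len(self.contours)
        train = np.zeros(n, dtype=bool)
        images = pd.Series(self.image_ids)
        for _, idx in images.groupby(images).groups.items():
            idx = np.asarray(idx)
            perm = rng.permutation(len(idx))
            n_train = max(1, int(round(self.train_fraction * len(idx))))
            train[idx[perm[:n_train]]] = True
        return train

    def fit(self, seed: int = 0, n_init: int = 10) -> "ShapeModeResults":
        """Fit PCA + k-means on the train split; assign every cell."""
        n = len(self.contours)
        if n < self.k:
            raise ParameterError(f"need at least k={self.k} cells, got {n}")
        vectors = np.array([register(resample_contour(np.asarray(c),
                                                      self.n_points))
                            for c in self.contours])
        rng = np.random.default_rng(seed)
        train = (self._split(rng) if self.train_fraction < 1
                 else np.ones(n, dtype=bool))
        if not train.any():
            raise ParameterError("empty train split")
        if int(train.sum()) < self.k:
            raise ParameterError("fewer training cells than modes")
        # resolve residual rotation/start ambiguity against the train mean
        _, ref = procrustes_align(vectors[train])
        vectors = np.array([align_to_reference(v, ref) for v in vectors])
        x_train = vectors[train]

        max_dim = min(len(x_train), vectors.shape[1])
        pca = PCA(n_components=max_dim, svd_solver="full")
        pca.fit(x_train)
        if self.n_components is None:
            ratios = np.cumsum(pca.explained_variance_ratio_)
            n_comp = int(np.searchsorted(ratios, 0.90) + 1)
            n_comp = min(n_comp, 20, max_dim)
        else:
            n_comp = min(self.n_components, max_dim)
        basis = pca.components_[:n_comp]
        mean_shape = pca.mean_
        scores = (vectors - mean_shape) @ basis.T

        km = KMeans(n_clusters=self.k, n_init=n_init,
                    random_state=int(seed) % (2**32))
        km.fit(scores[train])
        raw_labels = km.predict(scores)

        # renumber modes 1..k by decreasing median member area
        order = np.argsort([-np.median(self.areas[raw_labels == j])
                            if (raw_labels == j).any() else np.inf
                            for j in range(self.k)], kind="stable")
        centroids = km.cluster_centers_[order]
        relabel = np.empty(self.k, dtype=int)
        relabel[order] = np.arange(self.k)
        modes = relabel[raw_labels] + 1
        dists = np.linalg.norm(scores - centroids[modes - 1], axis=1)

        link = (_linkage(centroids, method="ward") if self.k >= 2
                else np.empty((0, 4)))
        model = ShapeModeModel(
            n_points=self.n_points, n_components=n_comp, k=self.k,
            mean_shape=mean_shape, alignment_reference=ref, basis=basis,
            explained_variance=pca.explained_variance_[:n_comp].copy(),
            explained_variance_ratio=pca.explained_variance_ratio_[:n_comp].copy(),
            centroids=centroids, linkage=link,
            train_fraction=self.train_fraction, seed=int(seed))
        assignments = pd.DataFrame({
            "cell_id": self.cell_ids,
            "image_id": self.image_ids,
            "shape_mode": modes,
            "distance_to_centroid": dists,
            "split": np.where(train, "train", "test"),
        })
        return ShapeModeResults(self, model, assignments, vectors)


@dataclass
class ShapeModeResults:
    """Fitted shape-mode model with per-cell assignments."""

    analysis: ShapeModeAnalysis
    model: ShapeModeModel
    assignments: pd.DataFrame
    registered_vectors: np.ndarray = field(repr=False)

    def mode_frequencies(self) -> pd.Series:
        """Percent of cells per mode over the whole population."""
        counts = self.assignments["shape_mode"].value_counts().sort_index()
        freq = counts.reindex(range(1, self.model.k + 1), fill_value=0)
        return 100.0 * freq / max(len(self.assignments), 1)

    def reconstruction_rms(self) -> float:
        """RMS residual of aligned registered vectors under the basis."""
        scores = (self.registered_vectors - self.model.mean_shape) @ self.model.basis.T
        recon = self.model.mean_shape + scores @ self.model.basis
        return float(np.sqrt(np.mean((recon - self.registered_vectors) ** 2)))

    def summary(self) -> str:
        m = self.model
        freq = self.mode_frequencies()
        lines = [
            "Shape-mode analysis (contour PCA + k-means)",
            "=" * 47,
            f"cells: {len(self.assignments)}   "
            f"train: {(self.assignments['split'] == 'train').sum()}   "
            f"test: {(self.assignments['split'] == 'test').sum()}",
            f"boundary points: {m.n_points}   PCA components: {m.n_components}"
            f" (explains {100 * m.explained_variance_ratio.sum():.1f}% variance)",
            f"shape modes (k): {m.k}   seed: {m.seed}",
            "",
            "mode   n      percent   median area (px)",
        ]
        areas = self.analysis.areas
        for mode in range(1, m.k + 1):
            sel = self.assignments["shape_mode"].to_numpy() == mode
            med = np.median(areas[sel]) if sel.any() else float("nan")
            lines.append(f"SM{mode:<4} {sel.sum():<6} {freq[mode]:>6.1f}%"
                         f"   {med:>10.1f}")
        _, leaves = m.dendrogram() if m.k >= 2 else (None, [1])
        lines.append("")
        lines.append("dendrogram leaf order: "
                     + " - ".join(f"SM{i}" for i in leaves))
        return "\n".join(lines)


def fit_model(contours, k: int = 5, n_points: int = 50,
              train_fraction: float = 0.8, seed: int = 0,
              **kwargs) -> tuple[ShapeModeModel, pd.DataFrame]:
    """Functional one-call interface: fit and return (model, assignments)."""
    res = ShapeModeAnalysis(contours, k=k, n_points=n_points,
                            train_fraction=train_fraction, **kwargs).fit(seed)
    return res.model, res.assignments


def render_mode_overlay(mask: LabeledMask | np.ndarray,
                        assignments: dict[int, int], k: int,
                        colormap: str = "twilight") -> np.ndarray:
    """Paint each cell by its shape-mode color; background stays black.

    ``assignments`` maps mask label -> mode (1..k).  Cells without an
    assignment are painted a reserved mid-gray.
    """
    import matplotlib

    labels = mask.labels if isinstance(mask, LabeledMask) else np.asarray(mask)
    cmap = matplotlib.colormaps[colormap]
    colors = (np.array([cmap((i + 0.5) / k)[:3] for i in range(k)]) * 255)
    out = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for lab in np.unique(labels[labels > 0]):
        mode = assignments.get(int(lab))
        if mode is None:
            out[labels == lab] = (128, 128, 128)
        else:
            if not 1 <= mode <= k:
                raise ParameterError(f"mode {mode} outside 1..{k}")
            out[labels == lab] = colors[mode - 1].astype(np.uint8)
    return out
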