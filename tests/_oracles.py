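"""Independent brute-force oracles used by the test suite.

Each thresholding oracle evaluates its method's defining criterion
exhaustively over all 8-bit gray levels, independent of any library
implementation.  Because a criterion can be flat across empty histogram
gaps, the optimizing oracles return the full *set* of optimal gray
levels; a threshold agrees with the oracle when it lies within one gray
level of that set.  The k-means oracle enumerates every partition.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage as ndi


def _hist(image: np.ndarray) -> np.ndarray:
    return np.bincount(np.asarray(image, dtype=np.uint8).ravel(),
                       minlength=256).astype(float)


def _argmax_set(values: np.ndarray) -> np.ndarray:
    """All integer gray levels within a relative 1e-12 of the optimum."""
    finite = np.isfinite(values)
    best = values[finite].max()
    tol = 1e-12 * max(abs(best), 1.0)
    return np.flatnonzero(finite & (values >= best - tol))


def _criterion_curve(image, func) -> np.ndarray:
    h = _hist(image)
    g = np.arange(256, dtype=float)
    out = np.full(256, -np.inf)
    for t in range(256):
        w0, w1 = h[: t + 1].sum(), h[t + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        out[t] = func(h, g, t, w0, w1)
    return out


def otsu_exhaustive(image: np.ndarray) -> np.ndarray:
    """Gray levels maximizing between-class variance."""
    def crit(h, g, t, w0, w1):
        mu0 = (g[: t + 1] * h[: t + 1]).sum() / w0
        mu1 = (g[t + 1:] * h[t + 1:]).sum() / w1
        return w0 * w1 * (mu0 - mu1) ** 2
    return _argmax_set(_criterion_curve(image, crit))


def isodata_exhaustive(image: np.ndarray) -> np.ndarray:
    """Gray levels closest to the midpoint of their two class means."""
    def crit(h, g, t, w0, w1):
        mu0 = (g[: t + 1] * h[: t + 1]).sum() / w0
        mu1 = (g[t + 1:] * h[t + 1:]).sum() / w1
        return -abs(t - (mu0 + mu1) / 2.0)
    return _argmax_set(_criterion_curve(image, crit))


def mean_exhaustive(image: np.ndarray) -> float:
    return float(np.mean(image))


def li_exhaustive(image: np.ndarray) -> np.ndarray:
    """Gray levels minimizing Li & Lee cross entropy.

    Minimizing the cross entropy reduces to maximizing
    S0·log μ0 + S1·log μ1 with S the class intensity sums; valid for
    strictly positive intensities (test fixtures use modes >= 1).
    """
    def crit(h, g, t, w0, w1):
        s0 = (g[: t + 1] * h[: t + 1]).sum()
        s1 = (g[t + 1:] * h[t + 1:]).sum()
        mu0, mu1 = s0 / w0, s1 / w1
        if mu0 <= 0 or mu1 <= 0:
            return -np.inf
        return s0 * np.log(mu0) + s1 * np.log(mu1)
    return _argmax_set(_criterion_curve(image, crit))


def yen_exhaustive(image: np.ndarray) -> np.ndarray:
    """Gray levels maximizing Yen's maximum-correlation criterion."""
    h = _hist(image)
    p = h / h.sum()
    p2 = p**2
    out = np.full(256, -np.inf)
    for t in range(256):
        p0 = p[: t + 1].sum()
        p1 = 1.0 - p0
        g0 = p2[: t + 1].sum()
        g1 = p2[t + 1:].sum()
        if p0 <= 0 or p1 <= 0 or g0 <= 0 or g1 <= 0:
            continue
        out[t] = -np.log(g0 * g1) + 2.0 * np.log(p0 * p1)
    return _argmax_set(out)


def triangle_exhaustive(image: np.ndarray) -> np.ndarray:
    """Gray levels farthest from the peak-to-tail chord of the histogram."""
    h = _hist(image)
    peak = int(np.argmax(h))
    nz = np.flatnonzero(h)
    lo, hi = int(nz[0]), int(nz[-1])
    # measure over the longer tail
    if peak - lo < hi - peak:
        t0, t1 = peak, hi
    else:
        t0, t1 = lo, peak
    x1, y1 = float(peak), float(h[peak])
    x2 = float(t1 if peak == t0 else t0)
    y2 = float(h[int(x2)])
    norm = np.hypot(x2 - x1, y2 - y1)
    out = np.full(256, -np.inf)
    for t in range(min(t0, t1), max(t0, t1) + 1):
        out[t] = abs((y2 - y1) * t - (x2 - x1) * h[t]
                     + x2 * y1 - y2 * x1) / norm
    return _argmax_set(out)


def minimum_exhaustive(image: np.ndarray, max_smoothings: int = 10000) -> int:
    """Valley between the two modes of the repeatedly smoothed histogram.

    The minimum method is defined procedurally (Prewitt & Mendelsohn):
    mean-filter the gray-level histogram (window 3, single precision,
    bins spanning the occupied intensity range) until at most two local
    maxima remain, then take the lowest smoothed count between them.
    This reimplements that procedure independently.
    """
    image = np.asarray(image)
    lo, hi = int(image.min()), int(image.max())
    levels = np.arange(lo, hi + 1)
    counts = np.bincount((image - lo).ravel(),
                         minlength=hi - lo + 1).astype(np.float32)

    def descending_turns(hist):
        # a maximum = point where the walk turns from ascent to descent
        maxima, direction = [], 1
        for i in range(len(hist) - 1):
            if direction > 0:
                if hist[i + 1] < hist[i]:
                    direction = -1
                    maxima.append(i)
            elif hist[i + 1] > hist[i]:
                direction = 1
        return maxima

    def run(h, lv):
        for _ in range(max_smoothings):
            h = ndi.uniform_filter1d(h, 3)
            maxima = descending_turns(h)
            if len(maxima) < 3:
                break
        if len(maxima) != 2:
            return None
        a, b = maxima
        return int(lv[a + int(np.argmin(h[a: b + 1]))])

    result = run(counts, levels)
    if result is None:
        # a mode at a terminal gray level: add empty guard bins
        result = run(np.concatenate([[0.0, 0.0], counts, [0.0, 0.0]]),
                     np.arange(lo - 2, hi + 3))
    if result is None:
        raise RuntimeError("histogram never became bimodal")
    return result


THRESHOLD_ORACLES = {
    "isodata": isodata_exhaustive,
    "li": li_exhaustive,
    "mean": mean_exhaustive,
    "minimum": minimum_exhaustive,
    "otsu": otsu_exhaustive,
    "triangle": triangle_exhaustive,
    "yen": yen_exhaustive,
}


def oracle_deviation(name: str, threshold: float, image: np.ndarray) -> float:
    """Distance from a computed threshold to the oracle's optimal set."""
    result = THRESHOLD_ORACLES[name](image)
    optimal = np.atleast_1d(np.asarray(result, dtype=float))
    return float(np.min(np.abs(optimal - threshold)))


def bimodal_image(seed: int, lo: float = 30.0, hi: float = 220.0,
                  sd: float = 10.0, frac_hi: float = 0.3,
                  size: int = 4096) -> np.ndarray:
    """Seeded 8-bit two-Gaussian mixture test image."""
    rng = np.random.default_rng(seed)
    n_hi = int(frac_hi * size)
    vals = np.concatenate([rng.normal(lo, sd, size - n_hi),
                           rng.normal(hi, sd, n_hi)])
    img = np.clip(np.round(vals), 0, 255).astype(np.uint8)
    side = int(np.sqrt(size))
    return img[: side * side].reshape(side, side)


def kmeans_exhaustive_inertia(points: np.ndarray, k: int) -> float:
    """Optimal k-means inertia by enumerating all label assignments."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    best = np.inf
    for labels in product(range(k), repeat=n):
        labels = np.asarray(labels)
        if len(set(labels.tolist())) < k:
            continue
        inertia = 0.0
        for j in range(k):
            sel = points[labels == j]
            inertia += ((sel - sel.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return float(best)
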