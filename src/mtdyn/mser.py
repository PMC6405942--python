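"""Maximally stable extremal regions (MSER) on the image component tree.

Bright-on-dark extremal regions are the connected components of the
threshold sets {x : f(x) >= t}.  These are exactly the nodes of the image
max-tree; a region is *maximally stable* when its relative area growth over
a threshold window ``delta`` is a local minimum along its branch.  The
max-tree itself comes from scikit-image; the stability analysis runs in
numba-compiled loops so full frames stay cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter
from skimage.morphology import max_tree

__all__ = ["MserConfig", "EllipseRegion", "detect_mser_regions"]


@dataclass(frozen=True)
class MserConfig:
    """Parameters of the MSER detector.

    ``delta`` is the stability window in gray levels of the 8-bit
    normalized image; ``min_area``/``max_area_frac`` bound region size in
    pixels / image fraction; ``max_variation`` is the maximal admissible
    relative area growth; ``smooth_sigma`` is an optional Gaussian
    pre-smoothing (px) that suppresses single-pixel Poisson extrema.
    """

    delta: int = 2
    min_area: int = 10
    max_area_frac: float = 0.10
    max_variation: float = 0.5
    smooth_sigma: float = 1.0
    connectivity: int = 2
    # regions whose gray level is below min_level_sigma * the robust
    # background noise scale are discarded as noise-born extrema
    min_level_sigma: float = 2.0


@dataclass
class EllipseRegion:
    """A detected region with its pixel set and second-moment ellipse.

    ``p``, ``r`` and ``q`` are the (x, y) variances and covariance of the
    pixel set; ``dr = sqrt(p^2 + 4 q^2 - 2 p r + r^2)`` is the eigenvalue
    discriminant of the 2x2 covariance matrix.
    """

    pixels: np.ndarray          # (N, 2) int array of (x, y)
    stability: float
    level: int                  # gray level of the component (normalized)

    centroid: np.ndarray = field(init=False)
    p: float = field(init=False)
    q: float = field(init=False)
    r: float = field(init=False)

    def __post_init__(self) -> None:
        xy = self.pixels.astype(float)
        self.centroid = xy.mean(axis=0)
        d = xy - self.centroid
        # 1/12 regularization: a single-pixel row still spans a pixel
        self.p = float(np.mean(d[:, 0] ** 2)) + 1.0 / 12.0
        self.r = float(np.mean(d[:, 1] ** 2)) + 1.0 / 12.0
        self.q = float(np.mean(d[:, 0] * d[:, 1]))

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def dr(self) -> float:
        return math.sqrt(self.p**2 + 4 * self.q**2
                         - 2 * self.p * self.r + self.r**2)

    @property
    def eigenvalues(self) -> tuple[float, float]:
        """(major, minor) eigenvalues (p + r +/- dr) / 2."""
        s, d = self.p + self.r, self.dr
        return ((s + d) / 2.0, (s - d) / 2.0)

    @property
    def major_axis_vector(self) -> np.ndarray:
        """Unit eigenvector of the larger eigenvalue, (2q, r - p + dr)."""
        v = np.array([2.0 * self.q, self.r - self.p + self.dr])
        n = np.linalg.norm(v)
        if n < 1e-12:
            # axis-aligned covariance: pick the axis of larger variance
            v = np.array([1.0, 0.0]) if self.p >= self.r else np.array([0.0, 1.0])
            return v
        return v / n

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1), inclusive-exclusive."""
        return (int(self.pixels[:, 0].min()), int(self.pixels[:, 1].min()),
                int(self.pixels[:, 0].max()) + 1,
                int(self.pixels[:, 1].max()) + 1)

    def contains(self, x: float, y: float) -> bool:
        xi, yi = int(round(x)), int(round(y))
        return bool(np.any((self.pixels[:, 0] == xi)
                           & (self.pixels[:, 1] == yi)))


# ---------------------------------------------------------------------------
# numba kernels over the flattened tree


@njit(cache=True)
def _canonical_and_area(parent, trav, value):
    n = parent.size
    canon = np.empty(n, np.int64)
    for i in range(n):
        p = trav[i]
        par = parent[p]
        if p == par or value[par] != value[p]:
            canon[p] = p
        else:
            canon[p] = canon[par]
    area = np.ones(n, np.int64)
    for i in range(n - 1, -1, -1):
        p = trav[i]
        par = parent[p]
        if par != p:
            area[par] += area[p]
    return canon, area


@njit(cache=True)
def _variation(parent, canon, value, area, delta):
    """Relative area growth over a ``delta`` gray-level window per node."""
    n = parent.size
    var = np.full(n, np.inf)
    for p in range(n):
        if canon[p] != p:
            continue
        t = value[p] - delta
        a = p
        while True:
            par = canon[parent[a]]
            if par == a or value[par] < t:
                break
            a = par
        var[p] = (area[a] - area[p]) / area[p]
    return var


@njit(cache=True)
def _local_minima(parent, canon, value, var, min_area, max_area, max_var,
                  area):
    n = parent.size
    child_min = np.full(n, np.inf)
    for p in range(n):
        if canon[p] != p:
            continue
        cp = canon[parent[p]]
        if cp != p and var[p] < child_min[cp]:
            child_min[cp] = var[p]
    sel = np.zeros(n, np.bool_)
    for p in range(n):
        if canon[p] != p:
            continue
        if area[p] < min_area or area[p] > max_area:
            continue
        if var[p] > max_var or not np.isfinite(var[p]):
            continue
        cp = canon[parent[p]]
        if cp != p and var[p] > var[cp]:
            continue
        if var[p] > child_min[p]:
            continue
        sel[p] = True
    return sel


@njit(cache=True)
def _pixel_labels(parent, trav, canon, keep_map):
    n = parent.size
    lab = np.full(n, -1, np.int64)
    for i in range(n):
        p = trav[i]
        c = canon[p]
        if keep_map[c] >= 0:
            lab[p] = keep_map[c]
        elif parent[p] != p:
            lab[p] = lab[parent[p]]
    return lab


def _normalize_u8(image: np.ndarray, smooth_sigma: float
                  ) -> tuple[np.ndarray, float] | None:
    """8-bit stretch (median..max) plus the noise scale in gray levels."""
    img = np.asarray(image, dtype=float)
    if smooth_sigma > 0:
        img = gaussian_filter(img, smooth_sigma)
    lo = float(np.median(img))
    hi = float(img.max())
    if hi - lo < 1e-12:
        return None
    sigma = 1.4826 * float(np.median(np.abs(img - lo)))
    q = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    return (q * 255.0).astype(np.uint8), sigma / (hi - lo) * 255.0


def detect_mser_regions(image: np.ndarray,
                        config: MserConfig | None = None) -> list[EllipseRegion]:
    """Detect maximally stable bright regions in a 2D image.

    Returns deduplicated regions (nested detections on one branch collapse
    to the most stable one), each carrying its pixel set, centroid and
    second moments.  A constant image yields an empty list.
    """
    if config is None:
        config = MserConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    norm = _normalize_u8(image, config.smooth_sigma)
    if norm is None:
        return []
    u8, noise_sigma = norm
    parent_img, trav = max_tree(u8, connectivity=config.connectivity)
    parent = parent_img.ravel().astype(np.int64)
    value = u8.ravel().astype(np.int64)
    trav = trav.astype(np.int64)

    canon, area = _canonical_and_area(parent, trav, value)
    var = _variation(parent, canon, value, area, config.delta)
    max_area = int(config.max_area_frac * u8.size)
    sel = _local_minima(parent, canon, value, var, config.min_area,
                        max_area, config.max_variation, area)
    cand = np.nonzero(sel)[0]
    min_level = config.min_level_sigma * noise_sigma
    cand = cand[value[cand] >= min_level]
    if cand.size == 0:
        return []

    # collapse nested candidates on a common branch: keep the most stable
    cand_set = set(int(c) for c in cand)
    chains: dict[int, set[int]] = {}
    for c in cand:
        anc = set()
        a = int(c)
        while True:
            par = int(canon[parent[a]])
            if par == a:
                break
            if par in cand_set:
                anc.add(par)
            a = par
        chains[int(c)] = anc
    order = sorted(cand, key=lambda c: (var[c], -area[c]))
    kept: list[int] = []
    kept_set: set[int] = set()
    for c in order:
        c = int(c)
        if chains[c] & kept_set:
            continue
        if any(c in chains[k] for k in kept):
            continue
        kept.append(c)
        kept_set.add(c)

    keep_map = np.full(parent.size, -1, np.int64)
    for idx, c in enumerate(kept):
        keep_map[c] = idx
    lab = _pixel_labels(parent, trav, canon, keep_map)

    w = u8.shape[1]
    regions: list[EllipseRegion] = []
    for idx, c in enumerate(kept):
        flat = np.nonzero(lab == idx)[0]
        xy = np.stack([flat % w, flat // w], axis=1)
        regions.append(EllipseRegion(pixels=xy, stability=float(var[c]),
                                     level=int(value[c])))
    return regions
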