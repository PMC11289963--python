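"""Shared fast 2D geometry kernels.

Star-blob polygons generated by the simulator are radial functions r(theta)
sampled at uniformly spaced angles, which admits O(1)-per-point containment
(exact ray/segment intersection in the point's angular sector) and
near-boundary-exact distance queries (point-to-segment distance over a
small angular window; the window can only overestimate, and only for
points far from the boundary).  Arbitrary polygons fall back to shapely.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import shapely
from shapely.geometry import Polygon

try:
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally installed
    HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _star_distance_nb(points, a, ab, ab_len2, cx, cy, theta0, window):  # pragma: no cover
    n_seg = a.shape[0]
    two_pi = 2.0 * np.pi
    out = np.empty(points.shape[0])
    for i in range(points.shape[0]):
        px, py = points[i, 0], points[i, 1]
        theta = (np.arctan2(py - cy, px - cx) - theta0) % two_pi
        j = int(theta / (two_pi / n_seg)) % n_seg
        best = 1e300
        for o in range(-window, window + 1):
            s = (j + o) % n_seg
            apx, apy = px - a[s, 0], py - a[s, 1]
            t = (apx * ab[s, 0] + apy * ab[s, 1]) / ab_len2[s]
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            dx = apx - t * ab[s, 0]
            dy = apy - t * ab[s, 1]
            d2 = dx * dx + dy * dy
            if d2 < best:
                best = d2
        out[i] = np.sqrt(best)
    return out


@_njit(cache=True)
def _star_contains_nb(points, a, ab, cx, cy, theta0):  # pragma: no cover
    n_seg = a.shape[0]
    two_pi = 2.0 * np.pi
    out = np.empty(points.shape[0], dtype=np.bool_)
    for i in range(points.shape[0]):
        px, py = points[i, 0], points[i, 1]
        rx, ry = px - cx, py - cy
        theta_abs = np.arctan2(ry, rx)
        theta = (theta_abs - theta0) % two_pi
        j = int(theta / (two_pi / n_seg)) % n_seg
        ux, uy = np.cos(theta_abs), np.sin(theta_abs)
        p1x, p1y = a[j, 0] - cx, a[j, 1] - cy
        denom = ux * ab[j, 1] - uy * ab[j, 0]
        numer = p1x * ab[j, 1] - p1y * ab[j, 0]
        rho_b = numer / denom if denom != 0.0 else -1.0
        # relative tolerance keeps exact-boundary points (e.g. grid nodes
        # on an axis-aligned edge) inside, matching the closed-mask rule
        out[i] = np.sqrt(rx * rx + ry * ry) <= rho_b * (1.0 + 1e-12) + 1e-12
    return out


class StarRing:
    """Containment and boundary-distance queries for a star-radial ring."""

    def __init__(self, ring_xy: np.ndarray, window: int = 3):
        self.a = np.ascontiguousarray(ring_xy, dtype=float)
        ab = np.roll(self.a, -1, axis=0) - self.a
        self.ab = np.ascontiguousarray(ab)
        self.ab_len2 = np.maximum((ab**2).sum(axis=1), 1e-300)
        self.center = self.a.mean(axis=0)
        self.n_seg = len(self.a)
        self.window = window
        self.offsets = np.arange(-window, window + 1)
        rel = self.a - self.center
        angles = np.arctan2(rel[:, 1], rel[:, 0])
        self.theta0 = float(angles[0])
        steps = np.diff(np.unwrap(angles))
        # radial parameterization holds iff vertex angles advance uniformly
        self.radial_ok = bool(
            np.all(steps > 0) and np.allclose(steps, 2 * np.pi / self.n_seg, rtol=1e-6)
        )

    def _sector(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rel = points - self.center
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        sector = ((theta - self.theta0) % (2 * np.pi)) / (2 * np.pi / self.n_seg)
        j = sector.astype(int) % self.n_seg
        return rel, theta % (2 * np.pi), j

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Exact point-in-star-polygon test (boundary inclusive)."""
        if HAVE_NUMBA:
            return _star_contains_nb(
                np.ascontiguousarray(points),
                self.a,
                self.ab,
                self.center[0],
                self.center[1],
                self.theta0,
            )
        rel, theta, j = self._sector(points)
        rho = np.hypot(rel[:, 0], rel[:, 1])
        u = np.column_stack([np.cos(theta), np.sin(theta)])
        p1 = self.a[j] - self.center
        d_seg = self.ab[j]
        denom = u[:, 0] * d_seg[:, 1] - u[:, 1] * d_seg[:, 0]
        numer = p1[:, 0] * d_seg[:, 1] - p1[:, 1] * d_seg[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            rho_boundary = numer / denom
        return rho <= rho_boundary * (1.0 + 1e-12) + 1e-12

    def distance(self, points: np.ndarray) -> np.ndarray:
        if HAVE_NUMBA:
            return _star_distance_nb(
                np.ascontiguousarray(points),
                self.a,
                self.ab,
                self.ab_len2,
                self.center[0],
                self.center[1],
                self.theta0,
                self.window,
            )
        _, _, j = self._sector(points)
        cand = (j[:, None] + self.offsets[None, :]) % self.n_seg
        ap = points[:, None, :] - self.a[cand]
        t = np.clip((ap * self.ab[cand]).sum(axis=2) / self.ab_len2[cand], 0.0, 1.0)
        closest = self.a[cand] + t[:, :, None] * self.ab[cand]
        d2 = ((points[:, None, :] - closest) ** 2).sum(axis=2)
        return np.sqrt(d2.min(axis=1))


def boundary_distance_fn(polygon: Polygon):
    """Callable mapping an (n, 2) array to exact distances to the exterior.

    Evaluates the point-to-segment minimum over the full exterior ring
    (a full-window star ring is an exact brute force for any polygon).
    """
    ring = np.asarray(polygon.exterior.coords)[:-1]
    return StarRing(ring, window=len(ring) // 2 + 1).distance


def contains_fn(polygon: Polygon):
    """Callable mapping an (n, 2) array to a boundary-inclusive in-polygon mask."""
    ring = np.asarray(polygon.exterior.coords)[:-1]
    star = StarRing(ring)
    if star.radial_ok and not polygon.interiors:
        return star.contains
    return lambda p: shapely.intersects_xy(
        polygon, np.asarray(p, float)[:, 0], np.asarray(p, float)[:, 1]
    )


def polygon_normalized_second_moment(polygon: Polygon) -> float:
    """Mean squared distance of the polygon's area to its centroid.

    Computed from the exact polar second moment of area (shoelace form);
    equals R^2/2 for a disc of radius R.
    """
    v = np.asarray(polygon.exterior.coords)
    x, y = v[:-1, 0], v[:-1, 1]
    x1, y1 = v[1:, 0], v[1:, 1]
    cross = x * y1 - x1 * y
    area = cross.sum() / 2.0
    ix = cross * (y**2 + y * y1 + y1**2)
    iy = cross * (x**2 + x * x1 + x1**2)
    j_origin = (ix.sum() + iy.sum()) / 12.0
    cx = (cross * (x + x1)).sum() / (6.0 * area)
    cy = (cross * (y + y1)).sum() / (6.0 * area)
    j_centroid = j_origin - area * (cx**2 + cy**2)
    return abs(j_centroid / area)


@lru_cache(maxsize=4096)
def _boundary_quantile_cached(wkb: bytes, q: float, grid: int) -> float:
    polygon = shapely.from_wkb(wkb)
    minx, miny, maxx, maxy = polygon.bounds
    gx = np.linspace(minx, maxx, grid)
    gy = np.linspace(miny, maxy, grid)
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = contains_fn(polygon)(pts)
    pts = pts[inside]
    d = boundary_distance_fn(polygon)(pts)
    return float(np.quantile(d, q))


def boundary_distance_quantile(polygon: Polygon, q: float = 0.75, grid: int = 48) -> float:
    """Area quantile of distance-to-boundary, on a deterministic in-cell grid."""
    return _boundary_quantile_cached(polygon.wkb, float(q), int(grid))
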