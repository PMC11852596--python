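"""Planar bounded point-set model: bounding box and minimum enclosing circle.

The length proxy used for a traced molecule is the diameter of the minimum
enclosing circle (MEC) of its centerline point set D.  The MEC is built by a
farthest-point-first iteration: start from the diametral pair of D, and while
some point lies outside the current circle, add the outside point farthest
from the centre to a working pool and recompute the smallest circle enclosing
the pool.  Because the pool only ever grows and the smallest circle of a
subset of D can never exceed the MEC of D, the iteration terminates at the
exact minimum enclosing circle.

``mec_oracle`` is a deliberately independent brute-force reference
(enumerate every 2-point diameter circle and 3-point circumcircle) used to
cross-check the iterative algorithm in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import EmptyInputError

__all__ = ["BoundingBox", "Circle", "bounding_box",
           "minimum_enclosing_circle", "mec_oracle"]

# collinearity guard: triples whose circumcircle determinant falls below this
# (relative to the squared span) degenerate to a 2-support circle
_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class BoundingBox:
    """Minimum axis-oriented bounding box {(x, y): x1<=x<=x2, y1<=y<=y2}."""

    x1: float
    x2: float
    y1: float
    y2: float

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return ((pts[:, 0] >= self.x1 - tol) & (pts[:, 0] <= self.x2 + tol)
                & (pts[:, 1] >= self.y1 - tol) & (pts[:, 1] <= self.y2 + tol))


@dataclass(frozen=True)
class Circle:
    """A circle with the <=3 input points that determine it."""

    center: tuple[float, float]
    radius: float
    support: tuple[tuple[float, float], ...]

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        d = np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
        return d <= self.radius + tol


def _as_points(D) -> np.ndarray:
    pts = np.asarray(D, dtype=float)
    if pts.size == 0:
        raise EmptyInputError("point set is empty")
    pts = pts.reshape(-1, 2)
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    return pts


def bounding_box(D) -> BoundingBox:
    """Axis-aligned extents of the point set (each face touches a point)."""
    pts = _as_points(D)
    return BoundingBox(x1=float(pts[:, 0].min()), x2=float(pts[:, 0].max()),
                       y1=float(pts[:, 1].min()), y2=float(pts[:, 1].max()))


def _circle_two(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2.0
    return c, float(np.hypot(*(p - c)))


def _circumcircle(a, b, c) -> tuple[np.ndarray, float] | None:
    """Circumcentre of a triangle, or None when (near-)collinear."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    span2 = max(np.sum((b - a) ** 2), np.sum((c - a) ** 2), np.sum((c - b) ** 2))
    if abs(d) <= _COLLINEAR_TOL * max(span2, 1.0):
        return None
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    center = np.array([ux, uy])
    r = float(np.max(np.hypot(*(np.vstack([a, b, c]) - center).T)))
    return center, r


def _smallest_circle_of_pool(pool: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact smallest enclosing circle of a small pool (brute force)."""
    n = len(pool)
    if n == 1:
        return pool[0].copy(), 0.0, pool[:1]
    span = float(np.ptp(pool, axis=0).max())
    tol = 1e-12 * max(span, 1.0)
    best = None
    for i, j in combinations(range(n), 2):
        center, r = _circle_two(pool[i], pool[j])
        if np.all(np.hypot(pool[:, 0] - center[0], pool[:, 1] - center[1])
                  <= r + tol):
            if best is None or r < best[1]:
                best = (center, r, pool[[i, j]])
    for i, j, k in combinations(range(n), 3):
        cc = _circumcircle(pool[i], pool[j], pool[k])
        if cc is None:
            continue
        center, r = cc
        if best is not None and r >= best[1]:
            continue
        if np.all(np.hypot(pool[:, 0] - center[0], pool[:, 1] - center[1])
                  <= r + tol):
            best = (center, r, pool[[i, j, k]])
    assert best is not None
    return best


def _farthest_pair(pts: np.ndarray) -> tuple[int, int, float]:
    """Brute-force diametral pair (centerlines have at most a few hundred points)."""
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return int(i), int(j), float(np.sqrt(d2[i, j]))


def _support_on_circle(candidates: np.ndarray, center: np.ndarray,
                       radius: float, tol: float) -> tuple[tuple[float, float], ...]:
    on = [tuple(p) for p in candidates
          if abs(np.hypot(*(p - center)) - radius) <= tol]
    return tuple(on[:3])


def minimum_enclosing_circle(D, eps: float = 1e-9) -> Circle:
    """Minimum enclosing circle by farthest-point-first iteration.

    Parameters
    ----------
    D : array-like of shape (n, 2)
        The planar point set (n >= 1).
    eps : float
        Containment tolerance, relative to the farthest-pair distance.
    """
    pts = _as_points(D)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if len(pts) == 1:
        p = tuple(pts[0])
        return Circle(center=p, radius=0.0, support=(p,))

    i, j, diam = _farthest_pair(pts)
    eps_abs = eps * max(diam, 1e-300)
    pool_idx = [i, j]
    center, radius = _circle_two(pts[i], pts[j])
    support = pts[[i, j]]
    for _ in range(len(pts)):
        dist = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
        outside = dist - radius
        k = int(np.argmax(outside))  # ties: lowest index (argmax convention)
        if outside[k] <= eps_abs:
            break
        if k in pool_idx:  # fp-degenerate; cannot make progress
            break
        pool_idx.append(k)
        center, radius, support = _smallest_circle_of_pool(pts[pool_idx])
    sup = _support_on_circle(support, center, radius, tol=max(eps_abs, 1e-12))
    return Circle(center=(float(center[0]), float(center[1])),
                  radius=float(radius), support=sup)


def mec_oracle(D) -> Circle:
    """Brute-force minimum enclosing circle (independent reference).

    Enumerates all 2-point diameter circles and 3-point circumcircles and
    returns the smallest that encloses D.  O(n^4); intended for n up to ~30.
    """
    pts = _as_points(D)
    n = len(pts)
    if n == 1:
        p = tuple(pts[0])
        return Circle(center=p, radius=0.0, support=(p,))
    span = float(np.ptp(pts, axis=0).max())
    tol = 1e-12 * max(span, 1.0)

    pi, pj = np.triu_indices(n, k=1)
    centers = (pts[pi] + pts[pj]) / 2.0
    radii = 0.5 * np.hypot(pts[pi, 0] - pts[pj, 0], pts[pi, 1] - pts[pj, 1])
    supports = [(pi[k], pj[k]) for k in range(len(pi))]

    if n >= 3:
        trip = np.array(list(combinations(range(n), 3)))
        a, b, c = pts[trip[:, 0]], pts[trip[:, 1]], pts[trip[:, 2]]
        d = 2.0 * (a[:, 0] * (b[:, 1] - c[:, 1]) + b[:, 0] * (c[:, 1] - a[:, 1])
                   + c[:, 0] * (a[:, 1] - b[:, 1]))
        ok = np.abs(d) > _COLLINEAR_TOL * max(span * span, 1.0)
        a2 = np.sum(a * a, axis=1)
        b2 = np.sum(b * b, axis=1)
        c2 = np.sum(c * c, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1])
                  + c2 * (a[:, 1] - b[:, 1])) / d
            uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0])
                  + c2 * (b[:, 0] - a[:, 0])) / d
        cc = np.column_stack([ux, uy])[ok]
        rr = np.hypot(a[ok, 0] - cc[:, 0], a[ok, 1] - cc[:, 1])
        centers = np.vstack([centers, cc])
        radii = np.concatenate([radii, rr])
        supports.extend(tuple(t) for t in trip[ok])

    dist = np.hypot(pts[:, 0][None, :] - centers[:, 0][:, None],
                    pts[:, 1][None, :] - centers[:, 1][:, None])
    encloses = np.all(dist <= radii[:, None] + tol, axis=1)
    radii_ok = np.where(encloses, radii, np.inf)
    best = int(np.argmin(radii_ok))
    if not np.isfinite(radii_ok[best]):
        raise RuntimeError("no enclosing candidate circle found")
    center = centers[best]
    sup = tuple(tuple(pts[s]) for s in supports[best])
    return Circle(center=(float(center[0]), float(center[1])),
                  radius=float(radii[best]), support=sup)
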