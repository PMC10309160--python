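"""Maximum inscribed circle (MIC), minimum circumscribed circle (MCC), and
the MIC/MCC roundness metric.

MCC is the exact minimum enclosing circle of a point set (expected-linear
randomized incremental construction on the convex hull, seeded for
determinism).  MIC is found on a mask's interior distance field: the
distance is measured to the traced boundary pixel centers — mirroring
contour-based inscribed-circle utilities — with optional sub-pixel
refinement by quadratic peak interpolation.  Both solvers therefore measure
against the same boundary point set, which keeps r_mic <= r_mcc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .shapes import BinaryMask, Contour
from .raster import trace_boundary

__all__ = [
    "CircleFit",
    "min_circumscribed_circle",
    "max_inscribed_circle",
    "mic_mcc_roundness",
    "extremal_circles_mask",
    "extremal_circles_contour",
]

_EPS = 1e-9


@dataclass(frozen=True)
class CircleFit:
    center: tuple[float, float]
    radius: float
    role: str  # "inscribed" | "circumscribed"


def _circle_from_2(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2.0
    return c, float(np.hypot(*(p - c)))


def _circle_from_3(
    p: np.ndarray, q: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, float] | None:
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.hypot(*(p - c)))


def _in_circle(p: np.ndarray, c: np.ndarray, r: float) -> bool:
    return math.hypot(p[0] - c[0], p[1] - c[1]) <= r + _EPS * (1.0 + r)


def min_circumscribed_circle(points: np.ndarray, seed: int = 0) -> CircleFit:
    """Exact minimum enclosing circle (smallest circle containing all
    points), by the expected-linear randomized incremental algorithm.

    Points interior to the convex hull cannot support the circle and are
    discarded first; the insertion order of the hull points is shuffled
    with ``seed`` for deterministic output.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one point")
    if pts.shape[0] == 1:
        return CircleFit((float(pts[0, 0]), float(pts[0, 1])), 0.0, "circumscribed")
    if pts.shape[0] > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear/degenerate input: keep all points
    rng = np.random.default_rng(seed)
    p = pts[rng.permutation(len(pts))]

    c, r = _circle_from_2(p[0], p[1])
    for i in range(2, len(p)):
        if _in_circle(p[i], c, r):
            continue
        # p[i] is on the boundary of the minimal circle of p[:i+1]
        c, r = _circle_from_2(p[0], p[i])
        for j in range(1, i):
            if _in_circle(p[j], c, r):
                continue
            c, r = _circle_from_2(p[j], p[i])
            for k in range(j):
                if _in_circle(p[k], c, r):
                    continue
                res = _circle_from_3(p[i], p[j], p[k])
                if res is not None:
                    c, r = res
    return CircleFit((float(c[0]), float(c[1])), float(r), "circumscribed")


def _quadratic_peak(patch: np.ndarray) -> tuple[float, float, float]:
    """Least-squares paraboloid through a 3x3 patch; returns (dy, dx, value)
    of the peak, with offsets clipped to [-1, 1]."""
    ys, xs = np.mgrid[-1:2, -1:2]
    A = np.column_stack(
        [np.ones(9), xs.ravel(), ys.ravel(), (xs**2).ravel(),
         (xs * ys).ravel(), (ys**2).ravel()]
    )
    coef, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
    c0, cx, cy, cxx, cxy, cyy = coef
    h = np.array([[2 * cxx, cxy], [cxy, 2 * cyy]])
    det = np.linalg.det(h)
    if det <= 0:  # not a proper maximum; stay on the grid point
        return 0.0, 0.0, float(patch[1, 1])
    dx, dy = np.linalg.solve(h, [-cx, -cy])
    dx = float(np.clip(dx, -1.0, 1.0))
    dy = float(np.clip(dy, -1.0, 1.0))
    val = float(
        c0 + cx * dx + cy * dy + cxx * dx**2 + cxy * dx * dy + cyy * dy**2
    )
    return dy, dx, max(val, float(patch[1, 1]))


#: center-to-center distances overshoot the region border by half a pixel
_BORDER_OFFSET = 0.5


def max_inscribed_circle(mask: BinaryMask, refine: bool = True) -> CircleFit:
    """Largest circle inscribed in the mask region, from the interior
    Euclidean distance field.

    The center is the foreground pixel maximizing the distance to the
    background (ties broken toward the smallest (y, x)); the radius is that
    distance minus half a pixel, converting the center-to-center distance
    into a distance to the region border (exact for axis-aligned borders).
    With ``refine`` the peak of the distance field is first interpolated by
    a local quadratic fit for a sub-pixel center and radius.
    """
    if not mask.grid.any():
        raise ValueError("mask has no foreground pixels")
    padded = np.zeros((mask.height + 2, mask.width + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask.grid
    dist = ndimage.distance_transform_edt(padded)
    flat = int(np.argmax(dist))  # first max in row-major = smallest (y, x)
    r0, c0 = np.unravel_index(flat, dist.shape)
    radius = float(dist[r0, c0])
    cy, cx = float(r0), float(c0)
    if refine and np.all(padded[r0 - 1 : r0 + 2, c0 - 1 : c0 + 2]):
        dy, dx, val = _quadratic_peak(dist[r0 - 1 : r0 + 2, c0 - 1 : c0 + 2])
        cy += dy
        cx += dx
        radius = val
    x0, y0 = mask.origin
    # the EDT on foreground is >= 1 everywhere, so the radius stays positive
    return CircleFit((cx - 1 + x0, cy - 1 + y0), radius - _BORDER_OFFSET, "inscribed")


def mic_mcc_roundness(mic: CircleFit, mcc: CircleFit) -> float:
    """Area ratio of the maximum inscribed to the minimum circumscribed
    circle: (r_mic / r_mcc)**2, capped at 1.

    On rasterized shapes the two radii are estimated by different routes
    (distance field vs enclosing circle of boundary centers), so sub-pixel
    discretization noise can push the raw ratio marginally above 1 on
    near-circular regions; the cap keeps the metric on its (0, 1] scale.
    """
    if mic.role != "inscribed" or mcc.role != "circumscribed":
        raise ValueError("expected an inscribed and a circumscribed CircleFit")
    if mcc.radius <= 0:
        raise ValueError("circumscribed radius must be positive")
    return min(1.0, (mic.radius / mcc.radius) ** 2)


def extremal_circles_mask(mask: BinaryMask, seed: int = 0) -> tuple[CircleFit, CircleFit]:
    """(MIC, MCC) of a mask: MIC on the boundary distance field, MCC as the
    minimum enclosing circle of the boundary pixel centers."""
    boundary = trace_boundary(mask)
    x0, y0 = mask.origin
    pts = np.column_stack([boundary[:, 1] + x0, boundary[:, 0] + y0]).astype(float)
    pts = np.unique(pts, axis=0)
    mcc = min_circumscribed_circle(pts, seed=seed)
    mic = max_inscribed_circle(mask)
    return mic, mcc


def extremal_circles_contour(
    contour: Contour, seed: int = 0, n_grid: int = 256
) -> tuple[CircleFit, CircleFit]:
    """(MIC, MCC) computed on sub-pixel contour vertices.

    MCC is the minimum enclosing circle of the vertices.  MIC is estimated
    by maximizing, over a dense interior grid with local refinement, the
    distance to the contour polyline (adequate for the ideal-geometry
    invariants; mask-based analysis should use :func:`extremal_circles_mask`).
    """
    from scipy.optimize import minimize
    from shapely.geometry import Point, Polygon

    v = contour.vertices
    mcc = min_circumscribed_circle(v, seed=seed)

    poly = Polygon(v)
    boundary = poly.exterior

    def signed_depth(p: np.ndarray) -> float:
        pt = Point(p[0], p[1])
        d = boundary.distance(pt)
        return d if poly.contains(pt) else -d

    xs = np.linspace(v[:, 0].min(), v[:, 0].max(), 33)
    ys = np.linspace(v[:, 1].min(), v[:, 1].max(), 33)
    best_p, best_d = None, -np.inf
    for px in xs:
        for py in ys:
            dd = signed_depth(np.array([px, py]))
            if dd > best_d:
                best_d, best_p = dd, np.array([px, py])
    res = minimize(
        lambda p: -signed_depth(p), best_p, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    mic = CircleFit((float(res.x[0]), float(res.x[1])), float(-res.fun), "inscribed")
    return mic, mcc
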