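"""Synthetic shape generation and rasterization.

Generates the simulation battery of circles and same-area ellipses sampled
as 300-point trigonometric contours, rasterizes sub-pixel contours onto a
pixel grid (pixel-center even-odd rule), upsamples masks, and produces
FAZ-like irregular blob contours for fixtures and demos.

Coordinate convention: pixel centers sit at integer coordinates, x to the
right, y down, 0-based.  A :class:`BinaryMask` records the contour-space
coordinate of the center of pixel ``grid[0, 0]`` in its ``origin`` field so
contour and mask coordinates are inter-convertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ShapeKind",
    "ShapeSpec",
    "Contour",
    "BinaryMask",
    "make_circle",
    "make_same_area_ellipses",
    "make_ellipse",
    "battery_radii",
    "generate_battery",
    "rasterize",
    "upsample_mask",
    "make_faz_blob",
    "DEFAULT_RATIOS",
    "DEFAULT_N_SAMPLES",
]

#: aspect ratios 10:8, 10:6, 10:4 expressed as minor/major
DEFAULT_RATIOS: tuple[float, ...] = (0.8, 0.6, 0.4)
DEFAULT_N_SAMPLES: int = 300


class ShapeKind(str, Enum):
    CIRCLE = "circle"
    ELLIPSE = "ellipse"


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of one synthetic circle or ellipse.

    ``semi_major``/``semi_minor`` are the semi-axes a, b in pixels;
    ``reference_radius`` is the radius r of the circle with the same area
    (pi*a*b == pi*r**2); ``axis_ratio`` is b/a.
    """

    kind: ShapeKind
    semi_major: float
    semi_minor: float
    reference_radius: float
    axis_ratio: float
    n_samples: int = DEFAULT_N_SAMPLES
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.semi_major <= 0 or self.semi_minor <= 0:
            raise ValueError("semi-axes must be positive")
        if self.semi_minor > self.semi_major + 1e-12:
            raise ValueError("semi_minor must not exceed semi_major")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        area = self.semi_major * self.semi_minor
        ref = self.reference_radius**2
        if abs(area - ref) > 1e-9 * max(ref, 1.0):
            raise ValueError(
                "same-area construction violated: a*b != reference_radius**2"
            )


@dataclass(frozen=True)
class Contour:
    """Closed, ordered polyline of sub-pixel (x, y) vertices."""

    vertices: np.ndarray  # (n, 2) float
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a contour needs at least 3 (x, y) vertices")
        if np.any(np.all(v == np.roll(v, -1, axis=0), axis=1)):
            raise ValueError("consecutive duplicate vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def x(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.vertices[:, 1]

    def __len__(self) -> int:
        return len(self.vertices)

    def reversed(self) -> "Contour":
        return Contour(self.vertices[::-1].copy(), self.closed)

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + [dx, dy], self.closed)


@dataclass
class BinaryMask:
    """2-D binary grid for a single foreground region.

    ``origin`` is the contour-space (x, y) of the center of ``grid[0, 0]``.
    """

    grid: np.ndarray  # (h, w) bool
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        self.grid = g.astype(bool)

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    def pixel_centers(self) -> np.ndarray:
        """(n, 2) contour-space (x, y) coordinates of foreground centers."""
        rr, cc = np.nonzero(self.grid)
        x0, y0 = self.origin
        return np.column_stack([cc + x0, rr + y0]).astype(float)


def _sample_params(n_samples: int) -> np.ndarray:
    # t = k*2pi/n, endpoint excluded: n distinct perimeter points
    return np.arange(n_samples) * (2.0 * math.pi / n_samples)


def make_circle(
    radius: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    center: tuple[float, float] = (0.0, 0.0),
) -> Contour:
    """Circle contour sampled as x = r cos t, y = r sin t."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    t = _sample_params(n_samples)
    return Contour(
        np.column_stack(
            [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
        )
    )


def make_ellipse(
    semi_major: float,
    semi_minor: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    center: tuple[float, float] = (0.0, 0.0),
) -> Contour:
    """Axis-aligned ellipse contour x = a cos t, y = b sin t."""
    if semi_major <= 0 or semi_minor <= 0:
        raise ValueError("semi-axes must be positive")
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    t = _sample_params(n_samples)
    return Contour(
        np.column_stack(
            [center[0] + semi_major * np.cos(t), center[1] + semi_minor * np.sin(t)]
        )
    )


def make_same_area_ellipses(
    reference_radius: float,
    ratios: Sequence[float] = DEFAULT_RATIOS,
    n_samples: int = DEFAULT_N_SAMPLES,
    center: tuple[float, float] = (0.0, 0.0),
) -> list[Contour]:
    """Ellipses with the same area as the reference circle.

    For aspect ratio q = b/a the semi-axes are a = r/sqrt(q), b = r*sqrt(q),
    so pi*a*b == pi*r**2 exactly.
    """
    if reference_radius <= 0:
        raise ValueError("reference_radius must be positive")
    out = []
    for q in ratios:
        if not 0 < q <= 1:
            raise ValueError(f"aspect ratio must be in (0, 1], got {q}")
        a = reference_radius / math.sqrt(q)
        b = reference_radius * math.sqrt(q)
        out.append(make_ellipse(a, b, n_samples, center))
    return out


def battery_radii(
    r_min: float = 2.0, r_max: float = 1000.0, count: int = 37, spacing: str = "log"
) -> np.ndarray:
    """The battery's circle radii: log-spaced from 2 to 1000 px by default,
    rounded to 4 significant figures."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if r_max < r_min:
        raise ValueError("max radius below min radius")
    if r_min < 1:
        raise ValueError("min radius must be >= 1")
    if count == 1:
        radii = np.array([r_min])
    elif spacing == "log":
        radii = np.geomspace(r_min, r_max, count)
    elif spacing == "linear":
        radii = np.linspace(r_min, r_max, count)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    # round to 4 significant figures
    mags = np.floor(np.log10(radii))
    return np.round(radii / 10**mags, 3) * 10**mags


def generate_battery(
    radii: Sequence[float] | None = None,
    ratios: Sequence[float] = DEFAULT_RATIOS,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> list[tuple[ShapeSpec, Contour]]:
    """The full simulation battery: for every radius, one circle plus one
    same-area ellipse per aspect ratio (37 x 4 = 148 shapes by default)."""
    if radii is None:
        radii = battery_radii()
    shapes: list[tuple[ShapeSpec, Contour]] = []
    for r in radii:
        spec = ShapeSpec(ShapeKind.CIRCLE, r, r, r, 1.0, n_samples)
        shapes.append((spec, make_circle(r, n_samples)))
        for q, contour in zip(
            ratios, make_same_area_ellipses(r, ratios, n_samples)
        ):
            a = r / math.sqrt(q)
            b = r * math.sqrt(q)
            shapes.append(
                (ShapeSpec(ShapeKind.ELLIPSE, a, b, r, q, n_samples), contour)
            )
    return shapes


def rasterize(contour: Contour, padding: int = 2) -> BinaryMask:
    """Rasterize a simple closed contour: a pixel is foreground iff its
    center lies inside the polygon under the even-odd rule.

    Implemented as an exact scanline: for each pixel row, horizontal
    crossings with all polygon edges are counted with a half-open rule
    (y1 <= yc < y2), which makes points exactly on an edge resolve
    deterministically (inside when approached from below/left).
    """
    v = contour.vertices
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)

    xmin = math.floor(v[:, 0].min()) - padding
    xmax = math.ceil(v[:, 0].max()) + padding
    ymin = math.floor(v[:, 1].min()) - padding
    ymax = math.ceil(v[:, 1].max()) + padding
    w = xmax - xmin + 1
    h = ymax - ymin + 1

    grid = np.zeros((h, w), dtype=bool)
    lo = np.minimum(y1, y2)
    hi = np.maximum(y1, y2)
    for row in range(h):
        yc = ymin + row
        hit = (lo <= yc) & (yc < hi)  # half-open: edge endpoints counted once
        if not np.any(hit):
            continue
        xc = x1[hit] + (yc - y1[hit]) * (x2[hit] - x1[hit]) / (y2[hit] - y1[hit])
        xc.sort()
        # even-odd fill between consecutive crossing pairs
        for a, b in zip(xc[0::2], xc[1::2]):
            c0 = math.ceil(a - xmin)
            c1 = math.floor(b - xmin)
            if b - xmin == c1 and b == math.floor(b):  # center exactly on
                c1 -= 1  # right crossing: outside (half-open in x)
            if c1 >= c0:
                grid[row, c0 : c1 + 1] = True
    if not grid.any():
        raise ValueError("degenerate contour rasterizes to an empty mask")
    return BinaryMask(grid, origin=(float(xmin), float(ymin)))


def upsample_mask(mask: BinaryMask, factor: int) -> BinaryMask:
    """Nearest-neighbour upsampling: each pixel becomes a factor x factor
    block; foreground count scales by factor**2."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return BinaryMask(mask.grid.copy(), mask.origin)
    grid = np.kron(mask.grid, np.ones((factor, factor), dtype=bool))
    return BinaryMask(grid, mask.origin)


def make_faz_blob(
    seed: int,
    mean_radius: float = 35.0,
    irregularity: float = 0.2,
    n_harmonics: int = 6,
    n_samples: int = 360,
    center: tuple[float, float] = (0.0, 0.0),
) -> Contour:
    """FAZ-like irregular blob: a radial-Fourier contour
    r(theta) = r0 * (1 + sum_k a_k cos(k theta + phi_k)), k = 2..n_harmonics,
    with |a_k| <= irregularity / k.

    The 1/k amplitude decay gives a smooth, FAZ-plausible border; a radial
    (star-shaped) polygon with r > 0 everywhere is always simple.
    """
    if mean_radius <= 2:
        raise ValueError("mean_radius must exceed 2 px")
    if not 0 <= irregularity < 0.5:
        raise ValueError("irregularity must be in [0, 0.5)")
    if n_harmonics < 2:
        raise ValueError("n_harmonics must be >= 2")
    rng = np.random.default_rng(seed)
    theta = _sample_params(n_samples)
    r = np.full(n_samples, 1.0)
    for k in range(2, n_harmonics + 1):
        a_k = rng.uniform(-irregularity / k, irregularity / k)
        phi_k = rng.uniform(0.0, 2.0 * math.pi)
        r += a_k * np.cos(k * theta + phi_k)
    if np.any(r <= 0):  # unreachable for irregularity < 0.5, n_harmonics <= ~12
        raise ValueError("blob radius went non-positive; reduce irregularity")
    r *= mean_radius
    return Contour(
        np.column_stack(
            [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
        )
    )
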