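# Methods

## What is being modeled

A FAZ measurement pipeline has three stages: a boundary (exact coordinates
or a binary mask), a perimeter/area estimator, and a shape metric built
from them. Each stage admits multiple conventions, and the conventions do
not commute: circularity `4πA/P²` inherits the full bias of whichever
perimeter estimator it is built on, and the two roundness definitions react
very differently to border detail. This package implements the stages
explicitly so their interactions can be measured rather than guessed.

The synthetic battery is the controlled experiment: circles of known radius
and same-area ellipses of known axis ratio, for which every metric has a
closed-form ideal value. Deviations measured on the battery are pure
algorithm bias, with no segmentation or imaging noise.

## Shape synthesis

- **Contours.** `x = a·cos t`, `y = b·sin t` at `n_samples = 300` uniform
  parameter values, endpoint excluded (300 distinct vertices). Same-area
  ellipses use `a = r/√q`, `b = r·√q` so `πab = πr²` exactly, with axis
  ratios `q ∈ {0.8, 0.6, 0.4}`.
- **Radii.** 37 radii from 2 to 1000 px. The spacing within that range is a
  free choice; we use logarithmic spacing rounded to 4 significant figures,
  because pixel-discretization bias is a function of *relative* pixel size,
  so small shapes — where the action is — should be sampled densely. The
  radius list is a config item (`spacing="linear"` or an explicit list are
  accepted), and the fitted inter-metric relationships are mildly sensitive
  to it.
- **Rasterization.** A pixel is foreground iff its center lies inside the
  polygon (even-odd rule), implemented as an exact per-row scanline with a
  half-open crossing rule (`y₁ ≤ y_c < y₂`, and a center lying exactly on a
  crossing is inside from the left, outside from the right). The tie-break
  matters only when pixel centers fall exactly on the contour (integer
  radii on the axes); it is deterministic and documented rather than
  "never happens". Pixel centers sit at integer coordinates, x right,
  y down; masks carry an `origin` so mask and contour coordinates
  inter-convert exactly.
- **FAZ-like blobs** (fixtures and demos): radial-Fourier contours
  `r(θ) = r₀(1 + Σₖ aₖ cos(kθ + φₖ))`, harmonics k = 2..6, amplitudes drawn
  uniformly within `±irregularity/k` from a seeded generator. The 1/k decay
  gives smooth, plausibly FAZ-shaped borders, and a radial function with
  r > 0 is always a simple curve. Defaults `mean_radius = 35 px`,
  `irregularity = 0.2` put the blob in the healthy-FAZ size range at a
  0.0099 mm/px scale. What the blobs do **not** emulate: segmentation
  noise, vessel-notch concavities, holes, or scanner-specific artifacts —
  so tests passing on blobs say nothing about segmentation quality, only
  about the metrology downstream of it.

## Estimators

- **Sub-pixel:** shoelace area and summed vertex distances (closing edge
  included). Theoretical ellipse perimeter by adaptive quadrature of the
  parametric speed (`scipy.integrate.quad`, relative tolerance 1e-12);
  tests cross-check against the complete elliptic integral `4aE(e²)`.
- **Boundary tracing:** Moore-neighbour tracing, 8-connected, clockwise,
  canonical start at the top-most then left-most foreground pixel, Jacob's
  stopping criterion. One-pixel-wide spurs are traversed out and back.
- **Chain-code perimeter** ("old" style): 1 per axial step, √2 per
  diagonal. Systematically ~5% high on smooth boundaries (diagonal
  staircases are counted at √2 instead of their true secant length).
- **Corner-weighted perimeter** ("new" style): `0.980·N_axial +
  1.406·N_diag − 0.091·N_corner` (Vossepoel–Smeulders weights; config
  items). Near-unbiased on smooth shapes (within 0.5% on a 500 px disk).
- **Traced crack perimeter** (particle-analysis style): length of the
  pixel-edge outline minus `2 − √2` per convex 90° corner (config item).
  The correction is exact for 45° staircases but undercorrects shallower
  slopes, leaving a stable ~5% overestimate on smooth shapes. That residual
  is not a bug to be calibrated away: it is precisely the offset that
  produces a coefficient ≈ 0.89 (≈ 1/1.06²) in the power law between the
  two software circularity conventions.
- **Ellipse fit:** second central moments of foreground pixel centers with
  the +1/12 per-pixel variance correction; `moment_normalized` axes are
  `4√eigenvalue`, `equal_area` rescales them to match the pixel count.
  Both share eigenvalue ratio, hence identical AR roundness (asserted to
  1e-9).
- **Circularity conventions:** `matlab_style` = corner-weighted perimeter,
  with an optional small-region correction `(1 − 0.5/ρ)²`, `ρ = P/2π + 0.5`
  (default on, disableable); `imagej_style` = traced crack perimeter,
  capped at 1. Sub-pixel circularity is never capped.
- **MCC:** exact minimum enclosing circle (expected-linear randomized
  incremental construction, convex-hull prefilter, seeded shuffle,
  1e-9 support tolerance), run on the traced boundary pixel centers.
- **MIC:** peak of the interior Euclidean distance transform (distance to
  background pixel centers), refined by a least-squares paraboloid over the
  3×3 neighbourhood (disableable), minus a half-pixel border offset that
  converts a center-to-center distance into a distance to the region
  border. The offset is exact for axis-aligned borders (a 21-px square
  yields exactly 10.5). Ties in the distance field break toward the
  smallest (y, x).
- **MIC/MCC roundness** is capped at 1: the two radii come from different
  routes, so discretization noise on near-circular regions can push the raw
  ratio marginally above 1.

## Fits and summaries

- **Percent difference** `|a−b| / ((a+b)/2) × 100`, theoretical vs
  measured, summarized as min/mean/max per method, plus an ordinary
  least-squares line of theoretical (y) on measured (x).
- **Power laws** `y = k·xᵖ` by least squares on `log y` vs `log x`; R² is
  reported in log space (where the fit is linear; a linear-space R² is
  emitted alongside). The headline fits are computed over each
  relationship's validity domain — minor diameter ≥ 6 px for
  MIC/MCC-vs-AR roundness, ≥ 16 px for the circularity relation — because
  below those diameters the pixel-domain metrics are quantization-dominated
  (capped circularities and near-zero inscribed radii scatter wildly and
  would describe the quantization floor, not the relationship). The
  unfiltered fit is always emitted as a sensitivity run.

## Degenerate inputs and edge cases

Masks must contain exactly one 4-connected foreground region; multi-region
masks raise (the caller selects the FAZ component). Holes contribute
nothing to area and are ignored by the outer-boundary perimeters. A single
pixel has chain-code perimeter 0 and traced perimeter `4√2 − 4`. Empty
rasterizations, non-positive axes, aspect ratios outside (0, 1], and blob
irregularity ≥ 0.5 raise `ValueError`.

## Known limitations

- The pixel-domain conventions are *styles*, not bug-for-bug replicas of
  any particular MATLAB or ImageJ release; all constants are config items.
- The AR > MIC/MCC dominance count is the one battery statistic that is
  sensitive to the relative bias between the MIC and MCC solvers at the
  half-pixel level. Under this package's self-consistent convention,
  rasterized circles sit just below the tie line and the count lands at
  144/148; estimator pairs with a relative bias of a fraction of a pixel
  can move it by roughly a dozen shapes. Treat the count as
  convention-dependent when comparing across implementations.
- Sub-pixel metrics for user-supplied masks are computed on the crack-edge
  boundary polygon — the only exactly representable border of a pixelized
  region — so "sub-pixel" there means exact polygon arithmetic, not
  recovered continuous geometry.
- Physical (mm) outputs require an explicit `--scale-mm-per-px`; no device
  default is assumed.
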