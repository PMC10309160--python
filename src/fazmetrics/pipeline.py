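"""Run every metric over the shape battery (or user masks) and compare.

Produces:

* per-shape measurement rows (one :class:`RegionMeasures` each, flattened
  into a pandas DataFrame / results CSV);
* percent-difference summaries between theoretical and measured area and
  perimeter values for the six measurement methods (sub-pixel area,
  pixel-count area, coordinate perimeter, chain-code perimeter,
  corner-weighted perimeter, traced crack perimeter);
* power-law fits between MIC/MCC and AR roundness and between the two
  software circularity conventions;
* the count of shapes whose AR roundness exceeds their MIC/MCC roundness.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import raster, subpixel
from .circles import CircleFit, extremal_circles_mask, mic_mcc_roundness
from .shapes import (
    DEFAULT_N_SAMPLES,
    DEFAULT_RATIOS,
    BinaryMask,
    Contour,
    ShapeKind,
    ShapeSpec,
    battery_radii,
    generate_battery,
    rasterize,
)

__all__ = [
    "BatteryConfig",
    "PowerLawFit",
    "PercentDiffSummary",
    "RegionMeasures",
    "measure_shape",
    "run_battery",
    "summarize_percent_differences",
    "fit_power_law",
    "relate_roundness",
    "relate_circularities",
    "count_ar_exceeds_micmcc",
    "measure_real_mask",
    "summarize_battery",
    "RESULTS_SCHEMA_VERSION",
]

RESULTS_SCHEMA_VERSION = "1"

#: minimum shape diameters (px) above which the fitted power laws hold
ROUNDNESS_VALIDITY_DIAMETER = 6.0
CIRCULARITY_VALIDITY_DIAMETER = 16.0


@dataclass(frozen=True)
class BatteryConfig:
    """Configuration of a battery run; defaults reproduce the standard
    37-radius x (circle + 3 ellipse) = 148-shape experiment."""

    r_min: float = 2.0
    r_max: float = 1000.0
    n_radii: int = 37
    spacing: str = "log"
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    n_samples: int = DEFAULT_N_SAMPLES
    padding: int = 2
    perimeter_weights: tuple[float, float, float] = raster.VOSSEPOEL_SMEULDERS_WEIGHTS
    crack_corner_correction: float = raster.CRACK_CORNER_CORRECTION
    small_region_correction: bool = True
    mic_refine: bool = True
    seed: int = 0

    def radii(self) -> np.ndarray:
        return battery_radii(self.r_min, self.r_max, self.n_radii, self.spacing)


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of y = k * x**p by least squares on log y vs log x."""

    coefficient: float
    exponent: float
    r_squared: float  # in log space, where the fit is linear
    r_squared_linear: float  # back-transformed, for transparency
    n_points: int
    fit_domain: str


@dataclass(frozen=True)
class PercentDiffSummary:
    method_name: str
    min_pct: float
    mean_pct: float
    max_pct: float
    linear_slope: float
    linear_intercept: float


@dataclass(frozen=True)
class RegionMeasures:
    """Every metric for one shape under all algorithms."""

    shape_id: str
    spec: ShapeSpec | None
    subpixel: subpixel.SubpixelMeasures
    raster: raster.RasterMeasures
    theoretical_area: float | None
    theoretical_perimeter: float | None
    mic: CircleFit
    mcc: CircleFit
    mic_mcc_roundness: float
    scale_mm_per_px: float | None = None


def measure_shape(
    spec: ShapeSpec | None,
    contour: Contour,
    config: BatteryConfig | None = None,
    shape_id: str = "shape",
) -> RegionMeasures:
    """Measure one synthetic shape with every algorithm.

    The contour feeds the sub-pixel metrics; its rasterization feeds the
    pixel-domain metrics and the extremal-circle solvers; the ShapeSpec (if
    given) supplies the theoretical values.
    """
    cfg = config or BatteryConfig()
    sp = subpixel.measure_contour(contour)
    mask = rasterize(contour, padding=cfg.padding)
    rm = raster.measure_mask(
        mask, apply_small_region_correction=cfg.small_region_correction
    )
    mic, mcc = extremal_circles_mask(mask, seed=cfg.seed)
    if not cfg.mic_refine:
        from .circles import max_inscribed_circle

        mic = max_inscribed_circle(mask, refine=False)
    theo_a = theo_p = None
    if spec is not None:
        theo_a, theo_p = subpixel.theoretical_measures(spec)
    return RegionMeasures(
        shape_id=shape_id,
        spec=spec,
        subpixel=sp,
        raster=rm,
        theoretical_area=theo_a,
        theoretical_perimeter=theo_p,
        mic=mic,
        mcc=mcc,
        mic_mcc_roundness=mic_mcc_roundness(mic, mcc),
    )


def _row(m: RegionMeasures) -> dict:
    spec = m.spec
    row = {
        "shape_id": m.shape_id,
        "kind": spec.kind.value if spec else "mask",
        "reference_radius": spec.reference_radius if spec else np.nan,
        "semi_major": spec.semi_major if spec else np.nan,
        "semi_minor": spec.semi_minor if spec else np.nan,
        "axis_ratio": spec.axis_ratio if spec else np.nan,
        "theoretical_area": m.theoretical_area,
        "theoretical_perimeter": m.theoretical_perimeter,
        "subpixel_area": m.subpixel.area,
        "subpixel_perimeter": m.subpixel.perimeter,
        "subpixel_circularity": m.subpixel.circularity_standard,
        "subpixel_circularity_iso_sqrt": m.subpixel.circularity_iso_sqrt,
        "area_px": m.raster.area_px,
        "perimeter_chain8": m.raster.perimeter_chain8,
        "perimeter_corner_weighted": m.raster.perimeter_corner_weighted,
        "perimeter_traced": m.raster.perimeter_traced,
        "circularity_matlab_style": m.raster.circularity_matlab_style,
        "circularity_imagej_style": m.raster.circularity_imagej_style,
        "ar_roundness": m.raster.ar_roundness,
        "major_axis": m.raster.major_axis,
        "minor_axis": m.raster.minor_axis,
        "mic_radius": m.mic.radius,
        "mcc_radius": m.mcc.radius,
        "mic_mcc_roundness": m.mic_mcc_roundness,
    }
    if m.scale_mm_per_px is not None:
        s = m.scale_mm_per_px
        row["scale_mm_per_px"] = s
        row["subpixel_area_mm2"] = m.subpixel.area * s**2
        row["subpixel_perimeter_mm"] = m.subpixel.perimeter * s
        row["area_mm2"] = m.raster.area_px * s**2
    return row


def run_battery(config: BatteryConfig | None = None, progress: bool = False) -> pd.DataFrame:
    """Measure the whole synthetic battery; one row per shape."""
    cfg = config or BatteryConfig()
    shapes = generate_battery(cfg.radii(), cfg.ratios, cfg.n_samples)
    rows = []
    for i, (spec, contour) in enumerate(shapes):
        if progress:  # pragma: no cover
            print(f"  shape {i + 1}/{len(shapes)}: r={spec.reference_radius:g} "
                  f"q={spec.axis_ratio:g}", flush=True)
        sid = f"{spec.kind.value}_r{spec.reference_radius:g}_q{spec.axis_ratio:g}"
        rows.append(_row(measure_shape(spec, contour, cfg, shape_id=sid)))
    return pd.DataFrame(rows)


_METHOD_COLUMNS = [
    ("subpixel_area", "theoretical_area", "polyarea-style area"),
    ("area_px", "theoretical_area", "pixel-count area"),
    ("subpixel_perimeter", "theoretical_perimeter", "coordinate perimeter"),
    ("perimeter_chain8", "theoretical_perimeter", "old (chain-code) perimeter"),
    ("perimeter_corner_weighted", "theoretical_perimeter", "new (corner-weighted) perimeter"),
    ("perimeter_traced", "theoretical_perimeter", "traced (crack) perimeter"),
]


def summarize_percent_differences(table: pd.DataFrame) -> list[PercentDiffSummary]:
    """Min/mean/max percent difference between theoretical and measured
    values for each method, plus the least-squares line of theoretical (y)
    on measured (x)."""
    if table["theoretical_area"].isna().any():
        raise ValueError("table must carry theoretical values for every row")
    out = []
    for col, theo_col, name in _METHOD_COLUMNS:
        measured = table[col].to_numpy(dtype=float)
        theo = table[theo_col].to_numpy(dtype=float)
        pct = np.array(
            [subpixel.percent_difference(t, m) for t, m in zip(theo, measured)]
        )
        slope, intercept = np.polyfit(measured, theo, 1)
        out.append(
            PercentDiffSummary(
                method_name=name,
                min_pct=float(pct.min()),
                mean_pct=float(pct.mean()),
                max_pct=float(pct.max()),
                linear_slope=float(slope),
                linear_intercept=float(intercept),
            )
        )
    return out


def fit_power_law(
    x: Sequence[float],
    y: Sequence[float],
    min_diameter_px: float = 0.0,
    diameters: Sequence[float] | None = None,
    domain_label: str | None = None,
) -> PowerLawFit:
    """Least-squares fit of log y = log k + p log x.

    Shapes with (minor) diameter below ``min_diameter_px`` are excluded when
    ``diameters`` is given.  R^2 is computed in log space; a linear-space
    R^2 is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive x and y")
    if min_diameter_px > 0:
        if diameters is None:
            raise ValueError("diameters required to apply a diameter threshold")
        keep = np.asarray(diameters, dtype=float) >= min_diameter_px
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("insufficient data: need >= 3 points after filtering")
    lx, ly = np.log(x), np.log(y)
    p, logk = np.polyfit(lx, ly, 1)
    pred = logk + p * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2_log = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    y_pred = np.exp(pred)
    ss_res_lin = float(np.sum((y - y_pred) ** 2))
    ss_tot_lin = float(np.sum((y - y.mean()) ** 2))
    r2_lin = 1.0 - ss_res_lin / ss_tot_lin if ss_tot_lin > 0 else 1.0
    label = domain_label or (
        f"minor diameter >= {min_diameter_px:g} px" if min_diameter_px > 0 else "all shapes"
    )
    return PowerLawFit(
        coefficient=float(np.exp(logk)),
        exponent=float(p),
        r_squared=float(np.clip(r2_log, 0.0, 1.0)),
        r_squared_linear=float(r2_lin),
        n_points=int(len(x)),
        fit_domain=label,
    )


def _minor_diameters(table: pd.DataFrame) -> np.ndarray:
    return 2.0 * table["semi_minor"].to_numpy(dtype=float)


def relate_roundness(table: pd.DataFrame, min_diameter_px: float = 0.0) -> PowerLawFit:
    """Power law of MIC/MCC roundness (y) on AR roundness (x)."""
    return fit_power_law(
        table["ar_roundness"],
        table["mic_mcc_roundness"],
        min_diameter_px,
        _minor_diameters(table) if min_diameter_px > 0 else None,
    )


def relate_circularities(table: pd.DataFrame, min_diameter_px: float = 0.0) -> PowerLawFit:
    """Power law of imagej-style circularity (y) on matlab-style (x)."""
    return fit_power_law(
        table["circularity_matlab_style"],
        table["circularity_imagej_style"],
        min_diameter_px,
        _minor_diameters(table) if min_diameter_px > 0 else None,
    )


def count_ar_exceeds_micmcc(table: pd.DataFrame) -> tuple[int, int]:
    """How many shapes have AR roundness strictly above MIC/MCC roundness."""
    ar = table["ar_roundness"].to_numpy(dtype=float)
    mm = table["mic_mcc_roundness"].to_numpy(dtype=float)
    return int((ar > mm).sum()), int(len(table))


def measure_real_mask(
    mask: BinaryMask,
    scale_mm_per_px: float | None = None,
    config: BatteryConfig | None = None,
    shape_id: str = "mask",
) -> RegionMeasures:
    """Measure a user-supplied binary FAZ mask.

    The sub-pixel-style metrics are computed on the crack-edge boundary
    polygon extracted from the mask (the exactly representable border of a
    pixelized region); physical mm/mm^2 values are derived from
    ``scale_mm_per_px`` when given.
    """
    if scale_mm_per_px is not None and scale_mm_per_px <= 0:
        raise ValueError("scale_mm_per_px must be positive")
    cfg = config or BatteryConfig()
    corners, _, _ = raster.trace_crack_outline(mask)
    # corner (row, col) -> contour (x, y); offset -0.5 puts pixel centers at
    # integers (a pixel spans center +- 0.5)
    x0, y0 = mask.origin
    contour = Contour(
        np.column_stack([corners[:, 1] + x0 - 0.5, corners[:, 0] + y0 - 0.5])
    )
    sp = subpixel.measure_contour(contour)
    rm = raster.measure_mask(
        mask, apply_small_region_correction=cfg.small_region_correction
    )
    mic, mcc = extremal_circles_mask(mask, seed=cfg.seed)
    return RegionMeasures(
        shape_id=shape_id,
        spec=None,
        subpixel=sp,
        raster=rm,
        theoretical_area=None,
        theoretical_perimeter=None,
        mic=mic,
        mcc=mcc,
        mic_mcc_roundness=mic_mcc_roundness(mic, mcc),
        scale_mm_per_px=scale_mm_per_px,
    )


def real_mask_row(m: RegionMeasures) -> dict:
    """Flatten a RegionMeasures from a real mask into one CSV/JSON row."""
    return _row(m)


def summarize_battery(table: pd.DataFrame, config: BatteryConfig | None = None) -> dict:
    """Headline summary of a battery table: Table-1-style block, the two
    power laws (all shapes plus sensitivity runs at the validity
    thresholds), and the AR > MIC/MCC count."""
    cfg = config or BatteryConfig()
    summaries = summarize_percent_differences(table)
    count, total = count_ar_exceeds_micmcc(table)

    def fit_block(fn, validity_diameter):
        # headline fit over the relationship's validity domain; the
        # unfiltered fit is emitted alongside as a sensitivity run
        block = {}
        for key, thr in (("headline", validity_diameter), ("all_shapes", 0.0)):
            try:
                block[key] = asdict(fn(table, thr))
            except ValueError as e:
                block[key] = {"error": str(e)}
        return block

    return {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "n_shapes": int(len(table)),
        "percent_differences": [asdict(s) for s in summaries],
        "roundness_power_law": fit_block(
            relate_roundness, ROUNDNESS_VALIDITY_DIAMETER
        ),
        "circularity_power_law": fit_block(
            relate_circularities, CIRCULARITY_VALIDITY_DIAMETER
        ),
        "ar_exceeds_micmcc": {"count": count, "total": total},
        "config": {
            **asdict(cfg),
            "radii": [float(r) for r in cfg.radii()],
        },
    }
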