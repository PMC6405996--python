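"""Ratiometric pHluorin calibration, pH-map inversion and sector profiling.

pHluorin is a dual-excitation GFP variant: the ratio of 525-nm emission under
386-nm excitation to that under 470-nm excitation increases linearly with pH
between pH 6 and 8.  A linear calibration fitted on cells equilibrated at
known pH (benzoate-clamped agarose patches) converts ratio images of
chemotactically accumulating cells into pH maps.  Spatial structure around a
circular attractant source is summarized by averaging cell abundance (edge
signal) and emission ratio over successive fixed-width distance zones
parallel to the source border, then aggregating sides and replicates into a
mean profile with a 95% t-confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "DEFAULT_VALID_RANGE",
    "DEFAULT_SECTOR_WIDTH_PX",
    "DEFAULT_ZONES_INSIDE",
    "DEFAULT_ZONES_OUTSIDE",
    "fit_calibration",
    "ratio_to_pH",
    "compute_ratio_image",
    "edge_abundance",
    "signed_distance_map",
    "sector_profile",
    "aggregate_replicates",
    "accumulation_summary",
]

#: pH range over which the ratio-pH relation is linear and the fit is valid.
DEFAULT_VALID_RANGE: tuple[float, float] = (6.0, 8.0)

DEFAULT_SECTOR_WIDTH_PX = 25
DEFAULT_ZONES_INSIDE = 3
DEFAULT_ZONES_OUTSIDE = 57

#: Camera pixel size at the 20x magnification used for source assays,
#: fixed by the 25 px = 2 um sector equivalence.
DEFAULT_PIXEL_SIZE_UM = 0.08


@dataclass(frozen=True)
class CalibrationPoint:
    """One (pH, emission ratio) calibration measurement."""

    pH: float
    ratio: float


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear ratio <-> pH mapping, ratio = slope * pH + intercept.

    ``slope`` must be positive (ratio increases with pH); ``valid_range`` is
    the pH interval over which the linear law holds.
    """

    slope: float
    intercept: float
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")

    def ratio_at(self, pH):
        """Forward map pH -> ratio."""
        return self.slope * np.asarray(pH, dtype=float) + self.intercept


def fit_calibration(
    points: Iterable[CalibrationPoint],
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE,
) -> CalibrationCurve:
    """Ordinary least-squares line through the in-range calibration points.

    Points with pH outside ``valid_range`` are excluded from the fit.  At
    least 3 in-range points spanning at least 1 pH unit are required; a fitted
    slope <= 0 is rejected as violating the sensor physics.
    """
    pts = [(p.pH, p.ratio) for p in points]
    lo, hi = valid_range
    used = [(ph, r) for ph, r in pts if lo <= ph <= hi]
    if len(used) < 3:
        raise ValueError(
            f"need at least 3 calibration points with pH in [{lo}, {hi}], got {len(used)}"
        )
    ph = np.array([u[0] for u in used])
    ratio = np.array([u[1] for u in used])
    if ph.max() - ph.min() < 1.0:
        raise ValueError("calibration points must span at least 1 pH unit")
    slope, intercept = np.polyfit(ph, ratio, 1)
    if slope <= 0:
        raise ValueError(f"fitted calibration slope {slope:.4g} <= 0; ratio must increase with pH")
    pred = slope * ph + intercept
    ss_res = float(np.sum((ratio - pred) ** 2))
    ss_tot = float(np.sum((ratio - ratio.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        valid_range=(float(lo), float(hi)),
        r_squared=float(r2),
    )


def ratio_to_pH(ratio, curve: CalibrationCurve):
    """Invert emission ratio(s) to pH: pH = (ratio - intercept) / slope.

    Returns ``(pH, extrapolated)`` where ``extrapolated`` flags values that
    fall outside the curve's valid range.  Works elementwise on arrays.
    """
    ratio = np.asarray(ratio, dtype=float)
    if not np.all(np.isfinite(ratio)):
        raise ValueError("ratio must be finite")
    pH = (ratio - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    tol = 1e-9 * max(1.0, abs(hi), abs(lo))  # boundary pHs are in range
    extrapolated = (pH < lo - tol) | (pH > hi + tol)
    if pH.ndim == 0:
        return float(pH), bool(extrapolated)
    return pH, extrapolated


def compute_ratio_image(img386, img470, min_denominator: float) -> np.ma.MaskedArray:
    """Per-pixel 386/470 excitation ratio with a validity mask.

    Pixels where the 470-nm channel falls below ``min_denominator`` are
    masked invalid rather than producing unstable or infinite ratios.  A
    sensible default for ``min_denominator`` is ~5x the background noise SD.
    """
    a = np.asarray(img386, dtype=float)
    b = np.asarray(img470, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if min_denominator <= 0:
        raise ValueError("min_denominator must be positive")
    invalid = b < min_denominator
    ratio = np.divide(a, b, out=np.zeros_like(a), where=~invalid)
    return np.ma.masked_array(ratio, mask=invalid)


def edge_abundance(image) -> np.ndarray:
    """Gradient-magnitude map of a single-channel image (cell-abundance proxy).

    3x3 Sobel derivatives along both axes combined in quadrature — the
    operator behind ImageJ's "find edges".  Dense fields of cells produce
    proportionally more edge signal, so zone sums of this map track the
    number of cells per zone.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("edge_abundance expects a single-channel 2-D image")
    gx = ndimage.sobel(img, axis=1)
    gy = ndimage.sobel(img, axis=0)
    return np.hypot(gx, gy)


def signed_distance_map(source_mask) -> np.ndarray:
    """Euclidean distance to the source border, negative inside the source.

    Computed with the exact Euclidean distance transform, so zones built on
    it run parallel to an arbitrarily shaped (e.g. round) border.
    """
    mask = np.asarray(source_mask, dtype=bool)
    if not mask.any():
        raise ValueError("source mask is empty")
    if mask.all():
        raise ValueError("source mask covers the whole frame")
    outside = ndimage.distance_transform_edt(~mask)
    inside = ndimage.distance_transform_edt(mask)
    return outside - inside


def sector_profile(
    value_map,
    source_mask,
    sector_width_px: int = DEFAULT_SECTOR_WIDTH_PX,
    n_inside: int = DEFAULT_ZONES_INSIDE,
    n_outside: int = DEFAULT_ZONES_OUTSIDE,
    valid_mask=None,
) -> pd.DataFrame:
    """Mean of ``value_map`` over fixed-width distance zones around the source.

    Zone ``k`` (k = 1..n_outside) collects pixels whose signed distance ``d``
    to the source border satisfies (k-1)*w <= d < k*w; zone ``-j``
    (j = 1..n_inside) collects -j*w < d <= -(j-1)*w inside the source.  Every
    in-range pixel belongs to exactly one zone.  Zones without valid pixels
    are flagged ``empty`` with mean NaN.

    Returns a DataFrame with columns ``zone``, ``distance_px`` (zone-center
    distance from the border), ``mean``, ``n_pixels``, ``empty``.
    """
    vmap = np.asarray(value_map, dtype=float)
    mask = np.asarray(source_mask, dtype=bool)
    if vmap.shape != mask.shape:
        raise ValueError(f"map shape {vmap.shape} != source mask shape {mask.shape}")
    if sector_width_px <= 0:
        raise ValueError("sector_width_px must be positive")
    d = signed_distance_map(mask)
    valid = np.isfinite(vmap)
    if valid_mask is not None:
        valid &= np.asarray(valid_mask, dtype=bool)
    if isinstance(value_map, np.ma.MaskedArray):
        valid &= ~np.ma.getmaskarray(value_map)

    w = float(sector_width_px)
    rows = []
    for zone in [-j for j in range(n_inside, 0, -1)] + list(range(1, n_outside + 1)):
        if zone < 0:
            in_zone = (d > zone * w) & (d <= (zone + 1) * w)
            center = (zone + 0.5) * w
        else:
            in_zone = (d >= (zone - 1) * w) & (d < zone * w)
            center = (zone - 0.5) * w
        sel = in_zone & valid
        n = int(sel.sum())
        rows.append(
            {
                "zone": zone,
                "distance_px": center,
                "mean": float(vmap[sel].mean()) if n else np.nan,
                "n_pixels": n,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)


def aggregate_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-measurement zone tables into a mean profile with 95% CI.

    Each table is one measurement (one side of one replicate); both imaged
    sides of each replicate enter as separate tables, so four replicates
    imaged on both sides contribute n = 8 measurements per zone.  The band
    half-width is ``t_{0.975, n-1} * SD / sqrt(n)`` per zone, computed over
    the measurements with a non-empty value for that zone.

    Returns a DataFrame with columns ``zone``, ``distance_px``, ``mean``,
    ``ci95``, ``n``.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 measurements to aggregate")
    ref = tables[0]
    for t in tables[1:]:
        if not np.array_equal(t["zone"].values, ref["zone"].values) or not np.allclose(
            t["distance_px"].values, ref["distance_px"].values
        ):
            raise ValueError("zone geometry differs between measurements")
    stacked = np.vstack([t["mean"].values for t in tables])  # (n_meas, n_zones)
    rows = []
    for j, (zone, dist) in enumerate(zip(ref["zone"], ref["distance_px"])):
        vals = stacked[:, j]
        vals = vals[np.isfinite(vals)]
        n = vals.size
        if n >= 2:
            m = float(vals.mean())
            sd = float(vals.std(ddof=1))
            ci = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
        elif n == 1:
            m, ci = float(vals[0]), np.nan
        else:
            m, ci = np.nan, np.nan
        rows.append({"zone": zone, "distance_px": dist, "mean": m, "ci95": ci, "n": n})
    return pd.DataFrame(rows)


def accumulation_summary(
    zone_table: pd.DataFrame,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    window_um: float = 30.0,
    value_col: str = "mean",
) -> float:
    """Total abundance within the first ``window_um`` outside the source edge.

    Sums the zone values whose centers lie at a positive distance of at most
    ``window_um`` micrometres from the border.  The outside zones present
    must cover the window.
    """
    outside = zone_table[zone_table["zone"] > 0]
    if outside.empty:
        raise ValueError("zone table contains no outside zones")
    dist_um = outside["distance_px"].values * pixel_size_um
    w = outside["distance_px"].values  # zone centers in px
    zone_width_um = (w[1] - w[0]) * pixel_size_um if len(w) > 1 else 2 * w[0] * pixel_size_um
    coverage = dist_um.max() + zone_width_um / 2
    if coverage < window_um:
        raise ValueError(
            f"outside zones cover only {coverage:.1f} um, need at least {window_um} um"
        )
    sel = dist_um <= window_um
    vals = outside.loc[sel, value_col].values
    return float(np.nansum(vals))
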