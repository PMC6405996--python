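"""Foci detection, cell-normalized localization and colocalization.

Split-eGFP foci report CheY~P-CheZ interactions; FliM-mCherry foci mark
flagellar motors.  Spots are detected per cell against the cell's own local
background, scored by amplitude over the robust noise level of that cell, and
placed on a normalized longitudinal axis (-1/+1 = poles, 0 = mid-cell).
Downstream summaries: polar/mid-cell partition, intensity histograms,
two-channel colocalization by one-to-one nearest matching, and slope tests of
per-position foci counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max

__all__ = [
    "CellRecord",
    "FocusRecord",
    "IntensityHistogram",
    "SlopeTestResult",
    "DEFAULT_SCORE_THRESHOLD",
    "DEFAULT_MAX_DIST_PX",
    "DEFAULT_POLAR_CUTOFF",
    "DEFAULT_PIXEL_SIZE_UM",
    "detect_foci",
    "normalize_position",
    "polar_fraction",
    "match_foci",
    "colocalization_fraction",
    "foci_count_by_position",
    "slope_test",
    "intensity_histogram",
]

#: Dimensionless focus-score retention threshold (inclusive).
DEFAULT_SCORE_THRESHOLD = 10.0
#: Colocalization radius: 2 px = 120 nm, the epifluorescence resolution limit.
DEFAULT_MAX_DIST_PX = 2.0
#: |normalized position| at or beyond which a focus counts as polar.
DEFAULT_POLAR_CUTOFF = 0.5
#: Pixel size at the 100x magnification used for foci imaging (2 px = 120 nm).
DEFAULT_PIXEL_SIZE_UM = 0.06


@dataclass(frozen=True)
class CellRecord:
    """A segmented cell: its pixel set and pole axis.

    ``pixels`` is an (N, 2) integer array of (row, col) mask coordinates;
    ``pole_axis`` holds the two long-axis endpoints as (x, y) = (col, row)
    pixel coordinates.
    """

    cell_id: int
    pixels: np.ndarray
    pole_axis: tuple[tuple[float, float], tuple[float, float]]
    length_um: float = 0.0

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass(frozen=True)
class FocusRecord:
    """A detected (or planted) fluorescent spot."""

    cell_id: int
    channel: str  # "eGFP" | "mCherry"
    position: tuple[float, float]  # (x, y) pixels
    intensity: float  # background-subtracted amplitude, arbitrary units
    score: float  # amplitude / robust cell-noise SD
    norm_pos: float = np.nan  # longitudinal position in [-1, 1]


@dataclass(frozen=True)
class IntensityHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    condition: str = ""
    position_label: str = ""


@dataclass(frozen=True)
class SlopeTestResult:
    slope: float
    stderr: float
    t: float
    p: float
    perfect_fit: bool = False


def _labels_image(cells: Sequence[CellRecord], shape) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    for cell in cells:
        labels[cell.pixels[:, 0], cell.pixels[:, 1]] = cell.cell_id
    return labels


def detect_foci(
    image,
    cells: Sequence[CellRecord],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    psf_sigma: float = 1.5,
    channel: str = "eGFP",
    smooth_sigma: float = 1.0,
) -> list[FocusRecord]:
    """Detect foci inside cell masks against each cell's local background.

    The image is lightly Gaussian-smoothed, candidate spots are the local
    maxima inside each cell mask, and each cell's local background is the
    median of its interior pixels outside exclusion disks of radius
    ``2 * psf_sigma`` around the candidates.  The focus score is the
    background-subtracted peak amplitude divided by the robust SD (1.4826 x
    median absolute deviation) of the same non-spot pixels; candidates with
    score >= ``score_threshold`` (inclusive) are retained, at most one focus
    per local maximum.

    Background statistics use the cell mask eroded by ``ceil(3 *
    smooth_sigma)`` pixels, so the intensity roll-off smoothing creates at
    the cell boundary does not inflate the noise estimate.
    """
    img = np.asarray(image, dtype=float)
    if score_threshold < 0:
        raise ValueError("score_threshold must be nonnegative")
    if not cells:
        return []
    for cell in cells:
        if np.any(cell.pixels[:, 0] >= img.shape[0]) or np.any(cell.pixels[:, 1] >= img.shape[1]):
            raise ValueError(f"cell {cell.cell_id} mask exceeds image shape {img.shape}")

    smoothed = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    labels = _labels_image(cells, img.shape)
    min_dist = max(1, int(round(psf_sigma)))
    peaks = peak_local_max(
        smoothed, min_distance=min_dist, labels=labels, exclude_border=False
    )
    peaks_by_cell: dict[int, list[tuple[int, int]]] = {}
    for r, c in peaks:
        peaks_by_cell.setdefault(int(labels[r, c]), []).append((int(r), int(c)))

    erode_iter = int(np.ceil(3 * smooth_sigma))
    interior = (
        ndimage.binary_erosion(labels > 0, iterations=erode_iter)
        if erode_iter > 0
        else labels > 0
    )

    out: list[FocusRecord] = []
    excl_r2 = (2.0 * psf_sigma) ** 2
    for cell in cells:
        cand = peaks_by_cell.get(cell.cell_id, [])
        if not cand:
            continue
        rows, cols = cell.pixels[:, 0], cell.pixels[:, 1]
        vals = smoothed[rows, cols]
        # non-spot pixels: outside every candidate's exclusion disk
        nonspot = np.ones(rows.size, dtype=bool)
        for r, c in cand:
            nonspot &= (rows - r) ** 2 + (cols - c) ** 2 > excl_r2
        # prefer interior non-spot pixels; fall back gracefully for tiny masks
        inner = nonspot & interior[rows, cols]
        if inner.any():
            bg_vals = vals[inner]
        elif nonspot.any():
            bg_vals = vals[nonspot]
        else:
            bg_vals = vals
        background = float(np.median(bg_vals))
        mad = float(np.median(np.abs(bg_vals - background)))
        robust_sd = 1.4826 * mad
        for r, c in sorted(cand):
            amplitude = float(smoothed[r, c] - background)
            if amplitude <= 0:
                continue
            score = amplitude / robust_sd if robust_sd > 0 else np.inf
            if score >= score_threshold:
                xc, yc = _refine_centroid(smoothed, r, c, background, radius=1)
                out.append(
                    FocusRecord(
                        cell_id=cell.cell_id,
                        channel=channel,
                        position=(xc, yc),
                        intensity=amplitude,
                        score=float(score),
                        norm_pos=normalize_position(cell, (float(c), float(r))),
                    )
                )
    return out


def _refine_centroid(img, r: int, c: int, background: float, radius: int = 1):
    """Sub-pixel spot center: background-subtracted intensity centroid."""
    r0, r1 = max(r - radius, 0), min(r + radius, img.shape[0] - 1)
    c0, c1 = max(c - radius, 0), min(c + radius, img.shape[1] - 1)
    patch = np.maximum(img[r0 : r1 + 1, c0 : c1 + 1] - background, 0.0)
    total = patch.sum()
    if total <= 0:
        return float(c), float(r)
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    return float((patch * cc).sum() / total), float((patch * rr).sum() / total)


def normalize_position(cell: CellRecord, position: tuple[float, float]) -> float:
    """Longitudinal position of a point along the cell's pole axis.

    Signed projection onto the axis divided by the half-axis length, so the
    two poles map to -1 and +1 and mid-cell to 0; clamped to [-1, 1].
    """
    (x0, y0), (x1, y1) = cell.pole_axis
    axis = np.array([x1 - x0, y1 - y0], dtype=float)
    norm2 = float(axis @ axis)
    if norm2 == 0:
        raise ValueError(f"cell {cell.cell_id}: degenerate pole axis (zero length)")
    rel = np.array([position[0] - x0, position[1] - y0], dtype=float)
    u = float(rel @ axis) / norm2  # 0 at one pole, 1 at the other
    return float(np.clip(2.0 * u - 1.0, -1.0, 1.0))


def polar_fraction(
    foci: Iterable[FocusRecord], polar_cutoff: float = DEFAULT_POLAR_CUTOFF
) -> float:
    """Fraction of foci with |normalized position| >= ``polar_cutoff``."""
    pos = np.asarray([f.norm_pos for f in foci], dtype=float)
    if pos.size == 0:
        raise ValueError("polar_fraction of an empty focus list is undefined")
    return float(np.mean(np.abs(pos) >= polar_cutoff))


def _positions(foci) -> np.ndarray:
    arr = np.asarray(
        [f.position if isinstance(f, FocusRecord) else f for f in foci], dtype=float
    )
    return arr.reshape(-1, 2)


def match_foci(
    fociA, fociB, max_dist: float = DEFAULT_MAX_DIST_PX
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching of A-foci to B-foci under a distance cutoff.

    Finds the assignment that maximizes the number of pairs with Euclidean
    center distance strictly below ``max_dist`` and, among those, minimizes
    the total distance (Hungarian algorithm on the thresholded distance
    matrix).  For well-separated spot patterns this coincides with matching
    each focus to its nearest free partner.  Returns (index_A, index_B) pairs.
    """
    A = _positions(fociA)
    B = _positions(fociB)
    if A.size == 0 or B.size == 0:
        return []
    d = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2))
    # a penalty larger than any achievable total real distance makes the
    # minimum-cost assignment also a maximum-cardinality one
    big = max_dist * (d.size + 1.0)
    cost = np.where(d < max_dist, d, big)
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] < max_dist]


def colocalization_fraction(
    fociA, fociB, max_dist: float = DEFAULT_MAX_DIST_PX
) -> float:
    """Fraction of A-channel foci with a one-to-one B partner within ``max_dist``.

    Matching is greedy by ascending pair distance (equivalent to the optimal
    assignment for well-separated spot patterns); the distance criterion is
    strict ("at less than" the resolution limit).  An empty A list is an
    error; an empty B list gives 0.
    """
    A = _positions(fociA)
    if A.shape[0] == 0:
        raise ValueError("colocalization_fraction: channel-A focus list is empty")
    B = _positions(fociB)
    if B.shape[0] == 0:
        return 0.0
    return len(match_foci(A, B, max_dist)) / A.shape[0]


def foci_count_by_position(
    cell_positions: pd.DataFrame, foci: Iterable[FocusRecord]
) -> pd.DataFrame:
    """Mean and SD of per-cell retained-focus counts per distance position.

    ``cell_positions`` must have columns ``cell_id`` and ``position`` (the
    distance-position label of the field of view each cell was imaged in).
    Cells without any retained focus count as zero.  Positions without cells
    are absent from the output.
    """
    cells = cell_positions[["cell_id", "position"]].copy()
    counts = pd.Series(
        [f.cell_id for f in foci], dtype="int64", name="cell_id"
    ).value_counts()
    cells["n_foci"] = cells["cell_id"].map(counts).fillna(0).astype(int)
    grouped = cells.groupby("position")["n_foci"]
    out = grouped.agg(mean_foci="mean", sd_foci=lambda s: s.std(ddof=1), n_cells="count")
    out["sd_foci"] = out["sd_foci"].fillna(0.0)
    return out.reset_index()


def slope_test(x, y) -> SlopeTestResult:
    """OLS slope with standard error and two-sided t-test against slope = 0.

    t = slope / SE with n - 2 degrees of freedom.  A perfect fit (SE = 0) is
    flagged: p is reported as 0 for a nonzero slope and 1 for a flat line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("slope test needs at least 3 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("slope test: all x values are equal")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = y.mean() - slope * x.mean()
    rss = float(np.sum((y - (slope * x + intercept)) ** 2))
    se = float(np.sqrt(rss / (n - 2) / sxx))
    if se == 0.0:
        return SlopeTestResult(
            slope=slope,
            stderr=0.0,
            t=0.0 if slope == 0 else np.inf * np.sign(slope),
            p=1.0 if slope == 0 else 0.0,
            perfect_fit=True,
        )
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return SlopeTestResult(slope=slope, stderr=se, t=float(t), p=p)


def intensity_histogram(
    foci: Iterable[FocusRecord],
    bin_edges,
    condition: str = "",
    position_label: str = "",
) -> IntensityHistogram:
    """Histogram of retained-focus intensities over right-open bins.

    The last bin is right-closed (numpy convention), so the counts total the
    number of foci within the overall edge range.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    intensities = np.asarray([f.intensity for f in foci], dtype=float)
    counts, _ = np.histogram(intensities, bins=edges)
    return IntensityHistogram(
        bin_edges=edges, counts=counts, condition=condition, position_label=position_label
    )
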