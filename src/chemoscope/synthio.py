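"""Seeded synthetic-data generators for every pipeline input.

Three generators emulate the three experimental configurations the pipeline
analyzes, each with full ground truth attached:

* :func:`gen_foci_traces` — per-focus fluorescence time series following the
  second-order photobleaching law, with optional linear renewal (new
  split-eGFP formation) and additive truncated-Gaussian noise.
* :func:`gen_ratio_scene` — a two-excitation-channel image of ellipse cells
  around a circular attractant source; cytoplasmic (or periplasmic) pH varies
  exponentially with distance from the source edge and cell density can peak
  near the source.
* :func:`gen_foci_scene` — one- or two-channel foci scenes with planted
  per-cell focus counts, a polar/mid-cell position mixture, Gaussian-PSF
  spots, and a planted fraction of channel-A foci duplicated into channel B.

All randomness flows through ``numpy.random.default_rng(spec.seed)``;
identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .focikinetics import FociTrace, second_order_decay
from .focimap import CellRecord
from .phratio import CalibrationCurve

__all__ = [
    "TraceSimSpec",
    "RatioSceneSpec",
    "FociSceneSpec",
    "RatioScene",
    "FociScene",
    "DEFAULT_CALIBRATION",
    "uniform_density",
    "peaked_density",
    "gen_foci_traces",
    "gen_ratio_scene",
    "gen_foci_scene",
]

#: Calibration used to render synthetic ratio scenes when none is supplied:
#: ratio = 0.3 * pH - 1.3, a positive-slope line through plausible pHluorin
#: excitation ratios (0.5 at pH 6, 1.1 at pH 8).
DEFAULT_CALIBRATION = CalibrationCurve(slope=0.3, intercept=-1.3)

#: Pixel sizes implied by the two imaging magnifications: 100x foci imaging
#: (2 px = 120 nm) and 20x source-assay imaging (25 px = 2 um).
FOCI_PIXEL_SIZE_UM = 0.06
RATIO_PIXEL_SIZE_UM = 0.08


# ---------------------------------------------------------------------------
# foci traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSimSpec:
    """Simulation spec for per-focus fluorescence decay traces.

    Rate constants are drawn from Normal(k_mean, k_sd) truncated at 0 and
    initial fluorescence from Normal(A0_mean, A0_sd) truncated just above 0.
    ``renewal_rate`` adds a linear replenishment term (arbitrary units per
    minute) that slows the apparent decay, emulating renewed split-eGFP
    formation in repellent-exposed cells.  The 1-minute default time grid
    matches the imaging cadence.
    """

    n_traces: int = 50
    k_mean: float = 0.05  # per minute
    k_sd: float = 0.01
    A0_mean: float = 3.0  # arbitrary units; ~2-fold decay over the 2-12 min window
    A0_sd: float = 0.3
    noise_sd: float = 0.06  # 2% of A0_mean
    renewal_rate: float = 0.0  # arbitrary units per minute
    t_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 13.0))
    seed: int = 0
    condition: str = "buffer"
    series: str = "0"

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        object.__setattr__(self, "t_grid", t)
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")
        if self.k_mean < 0:
            raise ValueError("k_mean must be >= 0")
        if self.A0_mean <= 0:
            raise ValueError("A0_mean must be > 0")
        if self.renewal_rate < 0:
            raise ValueError("renewal_rate must be >= 0")
        if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("t_grid must be 1-D and strictly increasing")


def gen_foci_traces(spec: TraceSimSpec) -> tuple[list[FociTrace], pd.DataFrame]:
    """Simulate foci traces; returns (traces, ground-truth table of k and A0).

    Each trace is ``1/(k t + 1/A0) + renewal_rate * t + noise``, clipped at
    zero.  The ground-truth DataFrame has columns ``focus_id``, ``k``, ``A0``.
    """
    rng = np.random.default_rng(spec.seed)
    ks = np.maximum(rng.normal(spec.k_mean, spec.k_sd, spec.n_traces), 0.0)
    A0s = np.maximum(rng.normal(spec.A0_mean, spec.A0_sd, spec.n_traces), 1e-6)
    traces = []
    rows = []
    for i, (k, A0) in enumerate(zip(ks, A0s)):
        fid = f"{spec.condition}-{spec.series}-{i:04d}"
        F = second_order_decay(spec.t_grid, k, A0) + spec.renewal_rate * spec.t_grid
        if spec.noise_sd > 0:
            F = F + rng.normal(0.0, spec.noise_sd, spec.t_grid.size)
        F = np.maximum(F, 0.0)
        traces.append(
            FociTrace(
                focus_id=fid,
                condition=spec.condition,
                t=spec.t_grid.copy(),
                F=F,
                series=spec.series,
            )
        )
        rows.append({"focus_id": fid, "k": float(k), "A0": float(A0)})
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared ellipse-cell geometry
# ---------------------------------------------------------------------------

def _ellipse_pixels(
    cy: float, cx: float, half_len: float, half_wid: float, angle: float, shape
) -> np.ndarray | None:
    """Integer (row, col) pixels of a rotated ellipse, or None if clipped."""
    pad = half_len + 1
    r0, r1 = int(np.floor(cy - pad)), int(np.ceil(cy + pad))
    c0, c1 = int(np.floor(cx - pad)), int(np.ceil(cx + pad))
    if r0 < 0 or c0 < 0 or r1 >= shape[0] or c1 >= shape[1]:
        return None
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    dy = rr - cy
    dx = cc - cx
    u = dx * np.cos(angle) + dy * np.sin(angle)  # along long axis
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    inside = (u / half_len) ** 2 + (v / half_wid) ** 2 <= 1.0
    return np.column_stack([rr[inside], cc[inside]])


def _place_cells(
    rng: np.random.Generator,
    shape,
    n_cells: int,
    half_len: float,
    half_wid: float,
    rotate: bool,
    pixel_size_um: float,
    position_sampler: Callable[[np.random.Generator], tuple[float, float]] | None = None,
    max_tries: int = 200,
) -> tuple[list[CellRecord], np.ndarray]:
    """Rejection-place non-overlapping ellipse cells; returns (cells, labels)."""
    labels = np.zeros(shape, dtype=np.int32)
    cells: list[CellRecord] = []
    margin = half_len + 2
    cell_id = 0
    for _ in range(n_cells):
        for _try in range(max_tries):
            if position_sampler is None:
                cy = rng.uniform(margin, shape[0] - margin)
                cx = rng.uniform(margin, shape[1] - margin)
            else:
                cy, cx = position_sampler(rng)
            angle = rng.uniform(0.0, np.pi) if rotate else 0.0
            px = _ellipse_pixels(cy, cx, half_len, half_wid, angle, shape)
            if px is None or np.any(labels[px[:, 0], px[:, 1]] != 0):
                continue
            cell_id += 1
            labels[px[:, 0], px[:, 1]] = cell_id
            p0 = (cx - half_len * np.cos(angle), cy - half_len * np.sin(angle))
            p1 = (cx + half_len * np.cos(angle), cy + half_len * np.sin(angle))
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    pixels=px,
                    pole_axis=(p0, p1),
                    length_um=2.0 * half_len * pixel_size_um,
                )
            )
            break
    return cells, labels


# ---------------------------------------------------------------------------
# ratio scenes
# ---------------------------------------------------------------------------

def uniform_density(level: float) -> Callable[[np.ndarray], np.ndarray]:
    """Constant expected cell density (cells per square micrometre)."""
    return lambda d_um: np.full_like(np.asarray(d_um, dtype=float), level)


def peaked_density(
    far: float, near: float, decay_length_um: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Density far + (near - far) * exp(-d / lambda): accumulation at the source."""
    def profile(d_um):
        d = np.asarray(d_um, dtype=float)
        return far + (near - far) * np.exp(-d / decay_length_um)

    return profile


@dataclass(frozen=True)
class RatioSceneSpec:
    """Spec for a two-excitation-channel source-attraction scene.

    The planted pH field decays exponentially from ``pH_near`` at the source
    edge to ``pH_far`` in the far field with length ``pH_decay_length_um``;
    per-cell emission ratios are the calibration applied to the cell-center
    pH.  ``cell_density_profile`` maps distance (um) to expected cells per
    square micrometre.  ``channel_noise_sd`` is additive Gaussian noise per
    channel in intensity units (the 470-channel cell signal is
    ``base_intensity``).
    """

    image_shape: tuple[int, int] = (420, 720)
    pixel_size_um: float = RATIO_PIXEL_SIZE_UM
    source_center: tuple[float, float] = (210.0, 110.0)  # (row, col)
    source_radius: float = 80.0  # pixels
    pH_far: float = 7.8
    pH_near: float = 7.8
    pH_decay_length_um: float = 20.0
    cell_density_profile: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: uniform_density(0.012)
    )
    calibration: CalibrationCurve = DEFAULT_CALIBRATION
    base_intensity: float = 100.0
    channel_noise_sd: float = 2.0
    cell_length_px: float = 28.0
    cell_width_px: float = 10.0
    rotate_cells: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.calibration.valid_range
        for name in ("pH_far", "pH_near"):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{name}={v} outside calibration valid range [{lo}, {hi}]"
                )
        if self.source_radius <= 0:
            raise ValueError("source_radius must be positive")
        if self.pH_decay_length_um <= 0:
            raise ValueError("pH_decay_length_um must be positive")


@dataclass(frozen=True)
class RatioScene:
    """Rendered two-channel scene with ground truth."""

    img386: np.ndarray
    img470: np.ndarray
    source_mask: np.ndarray
    labels: np.ndarray
    truth: pd.DataFrame  # cell_id, x, y, distance_px, distance_um, true_pH, true_ratio
    spec: RatioSceneSpec


def planted_pH(spec: RatioSceneSpec, distance_um) -> np.ndarray:
    """Closed-form planted pH field: far + (near - far) * exp(-d / lambda)."""
    d = np.asarray(distance_um, dtype=float)
    return spec.pH_far + (spec.pH_near - spec.pH_far) * np.exp(-d / spec.pH_decay_length_um)


def gen_ratio_scene(spec: RatioSceneSpec) -> RatioScene:
    """Render a dual-excitation scene of cells around a circular source.

    Both channels share identical cell placement.  Per cell, the 470-nm
    channel renders at ``base_intensity`` and the 386-nm channel at
    ``true_ratio * base_intensity``, so the noiseless per-cell channel ratio
    equals the calibration ratio at the planted pH.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist_px = np.hypot(rr - spec.source_center[0], cc - spec.source_center[1]) - spec.source_radius
    source_mask = dist_px <= 0

    half_len = spec.cell_length_px / 2.0
    half_wid = spec.cell_width_px / 2.0
    margin = half_len + 2

    # candidate cell centers: outside the source, inside the frame margin
    placeable = (
        (dist_px > half_wid)
        & (rr >= margin)
        & (rr < shape[0] - margin)
        & (cc >= margin)
        & (cc < shape[1] - margin)
    )
    d_um = np.maximum(dist_px, 0.0) * spec.pixel_size_um
    lam = spec.cell_density_profile(d_um) * (spec.pixel_size_um**2)
    lam = np.where(placeable, np.maximum(lam, 0.0), 0.0)
    total = float(lam.sum())
    n_cells = int(rng.poisson(total))
    flat_idx = rng.choice(lam.size, size=n_cells, replace=True, p=lam.ravel() / total)
    centers = [(float(i // shape[1]), float(i % shape[1])) for i in flat_idx]
    centers_iter = iter(centers)

    def sampler(_rng):
        return next(centers_iter)

    # one placement attempt per sampled center: overlapping draws are dropped
    cells, labels = _place_cells(
        rng,
        shape,
        n_cells,
        half_len,
        half_wid,
        spec.rotate_cells,
        spec.pixel_size_um,
        position_sampler=sampler,
        max_tries=1,
    )

    img470 = np.zeros(shape, dtype=float)
    img386 = np.zeros(shape, dtype=float)
    rows = []
    for cell in cells:
        (x0, y0), (x1, y1) = cell.pole_axis
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        d_cell_px = float(np.hypot(cy - spec.source_center[0], cx - spec.source_center[1]) - spec.source_radius)
        d_cell_um = max(d_cell_px, 0.0) * spec.pixel_size_um
        pH = float(planted_pH(spec, d_cell_um))
        ratio = float(spec.calibration.ratio_at(pH))
        img470[cell.pixels[:, 0], cell.pixels[:, 1]] = spec.base_intensity
        img386[cell.pixels[:, 0], cell.pixels[:, 1]] = ratio * spec.base_intensity
        rows.append(
            {
                "cell_id": cell.cell_id,
                "x": cx,
                "y": cy,
                "distance_px": d_cell_px,
                "distance_um": d_cell_um,
                "true_pH": pH,
                "true_ratio": ratio,
            }
        )
    if spec.channel_noise_sd > 0:
        img386 = np.maximum(img386 + rng.normal(0, spec.channel_noise_sd, shape), 0.0)
        img470 = np.maximum(img470 + rng.normal(0, spec.channel_noise_sd, shape), 0.0)
    truth = pd.DataFrame(
        rows,
        columns=["cell_id", "x", "y", "distance_px", "distance_um", "true_pH", "true_ratio"],
    )
    return RatioScene(
        img386=img386,
        img470=img470,
        source_mask=source_mask,
        labels=labels,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# foci scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FociSceneSpec:
    """Spec for a one- or two-channel foci scene.

    ``foci_per_cell_dist`` gives probabilities over 0..5 foci per cell (the
    observed per-cell range).  A planted focus is polar with probability
    ``polar_fraction`` (|normalized position| drawn in [0.6, 0.9]) and
    mid-cell otherwise (drawn in [-0.45, 0.45]).  With probability
    ``coloc_fraction`` a channel-A focus is duplicated into channel B with
    sub-pixel jitter of at most 1 px.
    """

    n_cells: int = 40
    image_shape: tuple[int, int] = (360, 360)
    cell_length_px: float = 30.0
    cell_width_px: float = 12.0
    foci_per_cell_dist: tuple[float, ...] = (0.1, 0.3, 0.3, 0.2, 0.08, 0.02)
    polar_fraction: float = 2.0 / 3.0
    focus_amplitude_mean: float = 30.0
    focus_amplitude_sd: float = 5.0
    psf_sigma: float = 1.5
    cell_level: float = 40.0
    background_level: float = 20.0
    background_noise_sd: float = 1.0
    coloc_fraction: float = 0.0
    two_channels: bool = False
    rotate_cells: bool = True
    pixel_size_um: float = FOCI_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.foci_per_cell_dist, dtype=float)
        if p.ndim != 1 or p.size > 6 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("foci_per_cell_dist must be probabilities over 0..5 summing to 1")
        if not 0.0 <= self.polar_fraction <= 1.0:
            raise ValueError("polar_fraction must lie in [0, 1]")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")


@dataclass(frozen=True)
class FociScene:
    """Rendered foci scene with per-cell and per-focus ground truth."""

    image_a: np.ndarray
    image_b: np.ndarray | None
    cells: list[CellRecord]
    labels: np.ndarray
    truth: pd.DataFrame  # focus_id, cell_id, channel, x, y, amplitude, norm_pos, has_partner
    spec: FociSceneSpec


def _add_spot(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    rad = int(np.ceil(4 * sigma))
    r0 = max(int(np.floor(y)) - rad, 0)
    r1 = min(int(np.ceil(y)) + rad, img.shape[0] - 1)
    c0 = max(int(np.floor(x)) - rad, 0)
    c1 = min(int(np.ceil(x)) + rad, img.shape[1] - 1)
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    img[r0 : r1 + 1, c0 : c1 + 1] += amp * np.exp(
        -((rr - y) ** 2 + (cc - x) ** 2) / (2.0 * sigma**2)
    )


def gen_foci_scene(spec: FociSceneSpec) -> FociScene:
    """Render a foci scene; channel A is eGFP, optional channel B is mCherry.

    Ground truth lists every planted focus exactly once, with its host cell,
    channel, planted center, amplitude, normalized longitudinal position, and
    whether an A-focus has a duplicated B partner.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    half_len = spec.cell_length_px / 2.0
    half_wid = spec.cell_width_px / 2.0
    cells, labels = _place_cells(
        rng, shape, spec.n_cells, half_len, half_wid, spec.rotate_cells, spec.pixel_size_um
    )

    img_a = np.full(shape, spec.background_level, dtype=float)
    img_b = np.full(shape, spec.background_level, dtype=float) if (
        spec.two_channels or spec.coloc_fraction > 0
    ) else None
    for cell in cells:
        img_a[cell.pixels[:, 0], cell.pixels[:, 1]] = spec.cell_level
        if img_b is not None:
            img_b[cell.pixels[:, 0], cell.pixels[:, 1]] = spec.cell_level

    p = np.asarray(spec.foci_per_cell_dist, dtype=float)
    rows = []
    focus_no = 0
    for cell in cells:
        (x0, y0), (x1, y1) = cell.pole_axis
        axis = np.array([x1 - x0, y1 - y0])
        axis_dir = axis / np.linalg.norm(axis)
        perp_dir = np.array([-axis_dir[1], axis_dir[0]])
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        n_foci = int(rng.choice(p.size, p=p))
        for _ in range(n_foci):
            if rng.random() < spec.polar_fraction:
                u = rng.uniform(0.6, 0.9) * (1 if rng.random() < 0.5 else -1)
            else:
                u = rng.uniform(-0.45, 0.45)
            # transverse offset scaled by the local ellipse half-width so the
            # focus center always falls inside the mask, poles included
            v = rng.uniform(-0.5, 0.5) * half_wid * np.sqrt(1.0 - u * u)
            pos = np.array([cx, cy]) + u * half_len * axis_dir + v * perp_dir
            amp = max(rng.normal(spec.focus_amplitude_mean, spec.focus_amplitude_sd), 1e-3)
            _add_spot(img_a, pos[0], pos[1], amp, spec.psf_sigma)
            has_partner = img_b is not None and rng.random() < spec.coloc_fraction
            rows.append(
                {
                    "focus_id": f"A-{focus_no:04d}",
                    "cell_id": cell.cell_id,
                    "channel": "eGFP",
                    "x": float(pos[0]),
                    "y": float(pos[1]),
                    "amplitude": float(amp),
                    "norm_pos": float(u),
                    "has_partner": bool(has_partner),
                }
            )
            if has_partner:
                theta = rng.uniform(0, 2 * np.pi)
                r = rng.uniform(0.0, 1.0)
                bpos = pos + r * np.array([np.cos(theta), np.sin(theta)])
                bamp = max(
                    rng.normal(spec.focus_amplitude_mean, spec.focus_amplitude_sd), 1e-3
                )
                _add_spot(img_b, bpos[0], bpos[1], bamp, spec.psf_sigma)
                rows.append(
                    {
                        "focus_id": f"B-{focus_no:04d}",
                        "cell_id": cell.cell_id,
                        "channel": "mCherry",
                        "x": float(bpos[0]),
                        "y": float(bpos[1]),
                        "amplitude": float(bamp),
                        "norm_pos": float(u),
                        "has_partner": True,
                    }
                )
            focus_no += 1
    if spec.background_noise_sd > 0:
        img_a = np.maximum(img_a + rng.normal(0, spec.background_noise_sd, shape), 0.0)
        if img_b is not None:
            img_b = np.maximum(img_b + rng.normal(0, spec.background_noise_sd, shape), 0.0)
    truth = pd.DataFrame(
        rows,
        columns=[
            "focus_id", "cell_id", "channel", "x", "y", "amplitude", "norm_pos", "has_partner",
        ],
    )
    return FociScene(
        image_a=img_a, image_b=img_b, cells=cells, labels=labels, truth=truth, spec=spec
    )
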