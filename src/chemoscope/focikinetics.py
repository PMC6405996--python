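"""Kinetic classification of split-eGFP focus fluorescence traces.

Focus fluorescence under continuous imaging decays mostly by photobleaching.
The decay of a single focus is modelled by the second-order decay law

    f(t) = 1 / (k * t + 1 / A0)

with rate constant ``k`` (per minute) and initial fluorescence ``A0``
(arbitrary units).  Traces recorded in plain motility buffer define the
bleaching baseline: the mean and standard deviation of their fitted rate
constants.  A focus in a ligand-exposed condition is called *slower* when its
rate constant (plus its own fitting deviation) falls below the baseline band,
which is the signature of renewed reporter formation counteracting bleach;
*faster* is the mirror case.  Per-series proportions of deviant foci are
compared across conditions with a Kruskal-Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FociTrace",
    "DecayFit",
    "BaselineStats",
    "DevianceResult",
    "KruskalWallisResult",
    "DEFAULT_FIT_WINDOW",
    "second_order_decay",
    "fit_second_order_decay",
    "fit_traces",
    "compute_baseline",
    "classify_deviance",
    "deviant_proportions",
    "kruskal_wallis",
]

#: Fit window in minutes; only samples with t inside this closed interval
#: enter the least-squares fit.
DEFAULT_FIT_WINDOW: tuple[float, float] = (2.0, 12.0)

#: Minimum number of in-window samples required for a fit (2 parameters
#: plus 2 residual degrees of freedom for the sd_k estimate).
MIN_FIT_SAMPLES = 4


@dataclass(frozen=True)
class FociTrace:
    """One focus's fluorescence-vs-time record.

    Parameters
    ----------
    focus_id : str
        Identifier of the focus.
    condition : str
        Experimental condition label (``buffer``, ``nickel``, ``serine`` ...).
    t : ndarray
        Sample times in minutes, strictly increasing.
    F : ndarray
        Mean focus fluorescence (arbitrary units), nonnegative.
    series : str
        Simultaneous sampling series the focus belongs to (used when
        aggregating deviant proportions).
    """

    focus_id: str
    condition: str
    t: np.ndarray
    F: np.ndarray
    series: str = "0"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "F", F)
        if t.ndim != 1 or F.shape != t.shape:
            raise ValueError(f"trace {self.focus_id}: t and F must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(f"trace {self.focus_id}: t must be strictly increasing")
        if np.any(F < 0):
            raise ValueError(f"trace {self.focus_id}: F must be nonnegative")


@dataclass(frozen=True)
class DecayFit:
    """Second-order decay fit of a single trace.

    ``sd_k`` is the per-trace fitting standard deviation of ``k``, taken from
    the curvature of the least-squares objective at the optimum.
    """

    focus_id: str
    k: float
    A0: float
    sd_k: float
    window: tuple[float, float] = DEFAULT_FIT_WINDOW
    rss: float = 0.0
    n_points: int = 0
    condition: str = "buffer"
    series: str = "0"


@dataclass(frozen=True)
class BaselineStats:
    """Buffer-population statistics of the fitted rate constant."""

    ave_k: float
    sd_k: float
    n: int


@dataclass(frozen=True)
class DevianceResult:
    focus_id: str
    deviance: str  # one of "slower", "baseline", "faster"
    condition: str = "buffer"
    series: str = "0"


@dataclass(frozen=True)
class KruskalWallisResult:
    H: float
    p: float
    #: True when any group has fewer than 5 values, where the chi-square
    #: approximation to the null distribution of H is unreliable.
    small_sample: bool = False


def second_order_decay(t, k, A0):
    """Evaluate f(t) = 1 / (k t + 1/A0)."""
    t = np.asarray(t, dtype=float)
    return 1.0 / (k * t + 1.0 / A0)


def _residuals(theta, t, F):
    k, b = theta
    den = k * t + b
    # keep the objective finite if the optimizer wanders across the pole
    den = np.where(np.abs(den) < 1e-12, 1e-12, den)
    return 1.0 / den - F


def fit_second_order_decay(
    trace: FociTrace, window: tuple[float, float] = DEFAULT_FIT_WINDOW
) -> DecayFit:
    """Fit ``F ~ 1/(k t + 1/A0)`` over the samples inside ``window``.

    The fit is run in the reparameterization ``(k, b=1/A0)``, which removes
    the singularity at A0 -> infinity, and initialized from the ordinary
    least-squares line through the reciprocal trace (the model is exactly
    linear in reciprocal space).  ``k`` may come out negative for a rising
    trace; ``A0`` is constrained positive.

    Raises
    ------
    ValueError
        If fewer than 4 samples fall inside the window.
    RuntimeError
        If the optimizer fails to converge (the message carries the last
        iterate).
    """
    lo, hi = float(window[0]), float(window[1])
    sel = (trace.t >= lo) & (trace.t <= hi)
    t, F = trace.t[sel], trace.F[sel]
    if t.size < MIN_FIT_SAMPLES:
        raise ValueError(
            f"trace {trace.focus_id}: only {t.size} samples inside window "
            f"[{lo}, {hi}], need at least {MIN_FIT_SAMPLES}"
        )

    # reciprocal-space initialization: 1/F = k t + b, weighted by F^2 so the
    # noisy small-F tail (whose reciprocal explodes) cannot dominate
    Fsafe = np.maximum(F, 1e-9)
    k0, b0 = np.polyfit(t, 1.0 / Fsafe, 1, w=Fsafe**2)
    # two-point fallback through the first and last in-window samples
    k_fb = (1.0 / Fsafe[-1] - 1.0 / Fsafe[0]) / (t[-1] - t[0])
    b_fb = 1.0 / Fsafe[0]
    if not (np.isfinite(k0) and np.isfinite(b0)):
        k0, b0 = k_fb, b_fb
    b0 = max(b0, 1e-9)

    res = None
    for x0 in ([k0, b0], [k_fb, max(b_fb, 1e-9)]):
        res = optimize.least_squares(
            _residuals,
            x0=x0,
            args=(t, F),
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=200,
        )
        if res.success:
            break
    if not res.success:
        raise RuntimeError(
            f"trace {trace.focus_id}: decay fit did not converge "
            f"(last iterate k={res.x[0]:.6g}, 1/A0={res.x[1]:.6g})"
        )
    k, b = res.x
    rss = float(2.0 * res.cost)

    # sd_k from the local curvature (Gauss-Newton covariance) at the optimum
    J = res.jac
    dof = max(t.size - 2, 1)
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        sd_k = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        sd_k = 0.0

    return DecayFit(
        focus_id=trace.focus_id,
        k=float(k),
        A0=float(1.0 / b),
        sd_k=sd_k,
        window=(lo, hi),
        rss=rss,
        n_points=int(t.size),
        condition=trace.condition,
        series=trace.series,
    )


def fit_traces(
    traces: Iterable[FociTrace], window: tuple[float, float] = DEFAULT_FIT_WINDOW
) -> list[DecayFit]:
    """Fit every trace; convenience wrapper over :func:`fit_second_order_decay`."""
    return [fit_second_order_decay(tr, window) for tr in traces]


def compute_baseline(fits: Sequence[DecayFit]) -> BaselineStats:
    """Mean and sample SD (n-1 denominator) of rate constants from buffer fits."""
    ks = np.asarray([f.k for f in fits], dtype=float)
    if ks.size < 2:
        raise ValueError(f"need at least 2 buffer fits for a baseline, got {ks.size}")
    return BaselineStats(ave_k=float(ks.mean()), sd_k=float(ks.std(ddof=1)), n=int(ks.size))


def classify_deviance(
    fit: DecayFit, baseline: BaselineStats, rule: str = "mirrored"
) -> DevianceResult:
    """Classify a focus as slower / baseline / faster relative to the buffer band.

    slower  iff  k + sd_k < ave_k - sd_k(baseline)   (decays less than expected)
    faster  iff  k - sd_k > ave_k + sd_k(baseline)   (decays more than expected)

    ``rule="printed"`` instead applies the literal published faster criterion
    ``k + sd_k > ave_k - sd_k(baseline)``, which classifies every non-slower
    trace as faster; it is retained only for fidelity checks.
    """
    slower = fit.k + fit.sd_k < baseline.ave_k - baseline.sd_k
    if slower:
        cls = "slower"
    elif rule == "mirrored":
        cls = "faster" if fit.k - fit.sd_k > baseline.ave_k + baseline.sd_k else "baseline"
    elif rule == "printed":
        cls = "faster" if fit.k + fit.sd_k > baseline.ave_k - baseline.sd_k else "baseline"
    else:
        raise ValueError(f"unknown deviance rule {rule!r}")
    return DevianceResult(
        focus_id=fit.focus_id, deviance=cls, condition=fit.condition, series=fit.series
    )


def deviant_proportions(results: Iterable[DevianceResult] | pd.DataFrame) -> pd.DataFrame:
    """Per (condition, series) proportions of slower / baseline / faster foci.

    Returns a DataFrame indexed by (condition, series) with columns
    ``prop_slower``, ``prop_baseline``, ``prop_faster`` and ``n``.  The three
    proportions sum to 1 in every row.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame(
            [
                {
                    "focus_id": r.focus_id,
                    "condition": r.condition,
                    "series": r.series,
                    "deviance": r.deviance,
                }
                for r in results
            ]
        )
    if df.empty:
        raise ValueError("no classified foci: every series must contain at least one focus")
    out = []
    for (cond, series), grp in df.groupby(["condition", "series"], sort=True):
        n = len(grp)
        counts = grp["deviance"].value_counts()
        out.append(
            {
                "condition": cond,
                "series": series,
                "prop_slower": counts.get("slower", 0) / n,
                "prop_baseline": counts.get("baseline", 0) / n,
                "prop_faster": counts.get("faster", 0) / n,
                "n": n,
            }
        )
    return pd.DataFrame(out).set_index(["condition", "series"])


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Kruskal-Wallis H test on two or more groups of per-series proportions.

    Mid-ranks are used for ties with the standard tie-correction factor; the
    p-value comes from the chi-square approximation with (groups - 1) degrees
    of freedom.  Identical pooled values give H = 0, p = 1.  The result is
    flagged ``small_sample`` when any group has fewer than 5 values.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    total = sum(a.size for a in arrays)
    if total < 3:
        raise ValueError("Kruskal-Wallis requires at least 3 values in total")
    small = any(a.size < 5 for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(H=0.0, p=1.0, small_sample=small)
    H, p = stats.kruskal(*arrays)
    return KruskalWallisResult(H=float(H), p=float(p), small_sample=small)
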