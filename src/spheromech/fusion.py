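"""Liquid-drop coalescence analysis of spheroid fusion.

Two fusing spheroids are modelled as coalescing highly viscous droplets
driven by surface tension.  The squared normalized neck radius evolves as

    (r0 / R0)^2 = 2^(2/3) * (1 - exp(-t / tau)),

where r0 is the neck radius, R0 the initial average radius of the pair and
tau the coalescence time constant.  Droplet theory links tau to the material
parameters through tau = 2^(2/3) * R0 * eta / Gamma, so the ratio
Gamma/eta = 2^(2/3) * R0 / tau — the visco-capillary velocity — measures
fusion speed independent of pair size.

Units follow the experimental convention: times in hours, lengths in µm,
visco-capillary velocity in µm/h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

__all__ = [
    "PLATEAU",
    "NeckSeries",
    "FusionFitResult",
    "GroupSummary",
    "fit_liquid_drop",
    "visco_capillary_velocity",
    "select_early_window",
    "aggregate_group",
]

#: t -> inf limit of (r0/R0)^2 for two equal coalescing drops.
PLATEAU: float = 2.0 ** (2.0 / 3.0)


@dataclass
class NeckSeries:
    """Measured (t, r0) trajectory of one fusing spheroid pair.

    ``neck_radius`` entries may be NaN where the measurement failed; those
    points are flagged missing and dropped from fits.
    """

    times: np.ndarray  # h, strictly increasing
    neck_radius: np.ndarray  # µm, NaN = missing
    R0: float  # µm, initial average radius of the pair
    radius_a: np.ndarray | None = None  # µm, per-frame lobe radii (optional)
    radius_b: np.ndarray | None = None
    pair_type: str = "synthetic"
    age_days: float = 7.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.neck_radius = np.asarray(self.neck_radius, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.neck_radius.shape:
            raise ValueError("times and neck_radius must be 1-D and congruent")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at or after 0")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        valid = ~np.isnan(self.neck_radius)
        if np.any(self.neck_radius[valid] < 0):
            raise ValueError("neck_radius must be non-negative where present")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.neck_radius)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class FusionFitResult:
    """Single-pair coalescence fit: tau, its standard error, and diagnostics."""

    tau: float  # h
    tau_se: float  # h
    visco_capillary_velocity: float  # µm/h, = 2^(2/3) R0 / tau
    adj_r2: float
    n_points: int
    window: tuple[float, float]  # h
    R0: float  # µm
    converged: bool = True
    amplitude: float | None = None  # fitted plateau if free_amplitude was used
    pair_type: str = ""


@dataclass
class GroupSummary:
    """Cohort-level summary of fusion fits for one pair type."""

    group: str
    n: int
    vcv_mean: float  # µm/h
    vcv_sd: float
    tau_mean: float  # h
    tau_sd: float
    r0_corr: float  # Pearson r of Gamma/eta vs R0
    r0_corr_p: float
    n_flagged: int = 0


def _model(t: np.ndarray, tau: float) -> np.ndarray:
    return PLATEAU * (1.0 - np.exp(-t / tau))


def _model_free(t: np.ndarray, tau: float, amplitude: float) -> np.ndarray:
    return amplitude * (1.0 - np.exp(-t / tau))


_TAU_BOUNDS = (1e-6, 1e6)
#: tau at (or effectively at) the upper bound means y never saturates: flagged.
_TAU_FLAG = 1e5


def fit_liquid_drop(
    series: NeckSeries,
    window: tuple[float, float] | None = None,
    free_amplitude: bool = False,
    weighting: str = "relative",
) -> FusionFitResult:
    """Fit the coalescence law to one neck trajectory.

    Nonlinear least squares on y = (r0/R0)^2 with tau the sole free
    parameter; the plateau prefactor is fixed at 2^(2/3) unless
    ``free_amplitude`` is set.

    ``weighting`` selects the objective:

    * ``"relative"`` (default) — least squares on log y, i.e. relative
      residuals.  Neck-radius measurement error is multiplicative (error
      scales with size), so this is the maximum-likelihood objective and
      roughly halves the tau scatter compared to absolute residuals.
      Non-positive y points carry no information about tau on this scale
      and are dropped.
    * ``"none"`` — plain unweighted least squares on y.

    The initial guess for tau is the time at which y first exceeds half of
    its final observed value (median time as fallback); on failure the fit
    restarts from spread guesses.  A fit whose tau runs away to the bound
    (trajectory never saturating, e.g. y = 0) is returned with
    ``converged=False`` and should be excluded from group statistics.
    The adjusted R² is always computed on the y scale, matching how fit
    quality is conventionally reported for these curves.
    """
    if weighting not in ("relative", "none"):
        raise ValueError("weighting must be 'relative' or 'none'")
    if window is None:
        window = (float(series.times.min()), float(series.times.max()))
    lo, hi = float(window[0]), float(window[1])
    mask = (~series.missing) & (series.times >= lo) & (series.times <= hi)
    n_free = 2 if free_amplitude else 1
    if mask.sum() < n_free + 2:
        raise ValueError(
            f"need at least {n_free + 2} non-missing points in window, got {int(mask.sum())}"
        )
    t_all = series.times[mask]
    y_all = (series.neck_radius[mask] / series.R0) ** 2
    if weighting == "relative":
        pos = y_all > 0
        t, y = t_all[pos], y_all[pos]
    else:
        t, y = t_all, y_all

    def flagged() -> FusionFitResult:
        return FusionFitResult(
            tau=np.inf,
            tau_se=np.inf,
            visco_capillary_velocity=0.0,
            adj_r2=np.nan,
            n_points=int(t.size),
            window=(lo, hi),
            R0=series.R0,
            converged=False,
            pair_type=series.pair_type,
        )

    if t.size < n_free + 2:
        return flagged()

    # initial guess: first time y exceeds half its final observed value
    y_final = y[-1]
    above = np.nonzero(y >= 0.5 * y_final)[0]
    if y_final > 0 and above.size:
        tau0 = max(float(t[above[0]]), 1e-3)
    else:
        tau0 = max(float(np.median(t)), 1e-3)

    if weighting == "relative":
        obs = np.log(y)
        model = (lambda tt, tau, amp: np.log(np.maximum(_model_free(tt, tau, amp), 1e-300))) \
            if free_amplitude else (lambda tt, tau: np.log(np.maximum(_model(tt, tau), 1e-300)))
    else:
        obs = y
        model = _model_free if free_amplitude else _model

    best = None
    for scale in (1.0, 0.2, 5.0):
        guess = float(np.clip(tau0 * scale, *_TAU_BOUNDS))
        p0 = [guess, PLATEAU] if free_amplitude else [guess]
        bounds = (
            ([_TAU_BOUNDS[0], 1e-6], [_TAU_BOUNDS[1], 10.0])
            if free_amplitude
            else ([_TAU_BOUNDS[0]], [_TAU_BOUNDS[1]])
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, t, obs, p0=p0, bounds=bounds, method="trf",
                    xtol=1e-12, ftol=1e-12, maxfev=10000,
                )
        except RuntimeError:
            continue
        cost = float(np.sum((obs - model(t, *popt)) ** 2))
        if best is None or cost < best[2]:
            best = (popt, pcov, cost)

    if best is None:
        return flagged()

    popt, pcov, _ = best
    tau = float(popt[0])
    amplitude = float(popt[1]) if free_amplitude else None
    tau_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    # goodness of fit reported on the y scale
    yhat = _model_free(t_all, *popt) if free_amplitude else _model(t_all, tau)
    ss_res = float(np.sum((y_all - yhat) ** 2))
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    n = t_all.size
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    p = n_free
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if np.isfinite(r2) else np.nan
    converged = tau < _TAU_FLAG and np.isfinite(tau_se)
    return FusionFitResult(
        tau=tau,
        tau_se=tau_se,
        visco_capillary_velocity=visco_capillary_velocity(tau, series.R0),
        adj_r2=adj_r2,
        n_points=n,
        window=(lo, hi),
        R0=series.R0,
        converged=converged,
        amplitude=amplitude,
        pair_type=series.pair_type,
    )


def visco_capillary_velocity(tau: float, R0: float) -> float:
    """Gamma/eta = 2^(2/3) * R0 / tau (µm/h for R0 in µm, tau in h)."""
    if tau <= 0 or R0 <= 0:
        raise ValueError("tau and R0 must be positive")
    return PLATEAU * R0 / tau


def select_early_window(
    series: NeckSeries,
    age_days: float | None = None,
    override: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Fit window for a series: [0, 6] h for compacting (≤3-day) spheroids.

    Young spheroids shrink during fusion, so only the early kinetics follow
    the constant-radius coalescence law; older pairs use the full record.
    An explicit ``override`` window wins.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    if override is not None:
        return (float(override[0]), float(override[1]))
    age = series.age_days if age_days is None else age_days
    if age <= 3:
        return (0.0, 6.0)
    return (0.0, float(series.times.max()))


def aggregate_group(
    results: Sequence[FusionFitResult],
    radii: Sequence[float] | None = None,
    group: str = "",
) -> GroupSummary:
    """Mean ± SD of Gamma/eta and tau over unflagged pairs, plus the
    Pearson correlation test of Gamma/eta against R0 (two-sided)."""
    results = list(results)
    if radii is None:
        radii = [r.R0 for r in results]
    if len(radii) != len(results):
        raise ValueError("radii must match results")
    ok = [i for i, r in enumerate(results) if r.converged]
    n_flagged = len(results) - len(ok)
    if len(ok) < 2:
        warnings.warn("fewer than 2 unflagged fits; empty group summary")
        return GroupSummary(group, len(ok), np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, n_flagged)
    vcv = np.array([results[i].visco_capillary_velocity for i in ok])
    tau = np.array([results[i].tau for i in ok])
    r0 = np.array([radii[i] for i in ok], dtype=float)
    if np.ptp(vcv) > 0 and np.ptp(r0) > 0:
        corr, corr_p = pearsonr(vcv, r0)
    else:
        corr, corr_p = np.nan, np.nan
    return GroupSummary(
        group=group,
        n=len(ok),
        vcv_mean=float(vcv.mean()),
        vcv_sd=float(vcv.std(ddof=1)),
        tau_mean=float(tau.mean()),
        tau_sd=float(tau.std(ddof=1)),
        r0_corr=float(corr) if np.isfinite(corr) else np.nan,
        r0_corr_p=float(corr_p) if np.isfinite(corr_p) else np.nan,
        n_flagged=n_flagged,
    )
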