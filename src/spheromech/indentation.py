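"""Nanoindentation force-curve analysis for soft tissue surfaces.

A spherical probe (radius R) is driven into the sample (load), held
(dwell) and withdrawn (retract).  Two inversions are provided:

* **Hertz** — the loading segment up to a shallow depth (default 10% of the
  tip radius) fit with the elastic contact law

      F = (4/3) * E / (1 - nu^2) * delta^(3/2) * sqrt(R),

  giving an apparent Young's modulus E.

* **Ting / power-law rheology (PLR)** — the complete cycle inverted with
  Ting's viscoelastic generalization of Hertz contact.  The relaxation
  modulus is E(t) = E1 * t^(-alpha) (E1 = modulus at 1 s; alpha = 0
  solid-like, alpha -> 1 fluid-like).  While the contact radius grows,

      F(t) = [4 sqrt(R) / (3 (1 - nu^2))] ∫_0^t E(t - xi) d(delta^(3/2))/dxi dxi,

  and during retraction the integral is truncated at the auxiliary time
  t1(t) defined by ∫_{t1}^{t} E(t - xi) (d delta/d xi) dxi = 0, with t1
  non-increasing in t.  The weakly singular kernel (t - xi)^(-alpha) is
  integrated analytically interval-by-interval against a piecewise-linear
  d(delta^(3/2))/dxi, so no pointwise evaluation at zero lag occurs.

All quantities are SI internally (m, s, N, Pa); reports convert to kPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import beta as beta_fn, betainc

__all__ = [
    "IndentationCurve",
    "HertzFitResult",
    "PLRFitResult",
    "ContactPoint",
    "hertz_force",
    "closed_form_ramp_force",
    "ting_forward",
    "detect_contact_point",
    "fit_hertz",
    "fit_plr",
    "summarize_sample",
]

PHASES = ("approach", "load", "dwell", "retract")


@dataclass
class IndentationCurve:
    """One load–dwell–retract record.

    ``depth`` is the probe position relative to the sample surface:
    negative before contact (approach), positive indentation after.  Phase
    labels are contiguous in the order approach → load → dwell → retract
    (approach optional).
    """

    time: np.ndarray  # s
    depth: np.ndarray  # m
    force: np.ndarray  # N
    phase: np.ndarray  # str labels from PHASES
    tip_radius: float  # m
    nu: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.phase = np.asarray(self.phase)
        n = self.time.size
        if not (self.depth.size == n and self.force.size == n and self.phase.size == n):
            raise ValueError("time, depth, force, phase must be congruent")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.tip_radius <= 0:
            raise ValueError("tip_radius must be positive")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must be in [0, 0.5]")
        order = [p for p in PHASES if np.any(self.phase == p)]
        idx = [np.nonzero(self.phase == p)[0] for p in order]
        for block in idx:
            if block.size and np.any(np.diff(block) != 1):
                raise ValueError("phases must be contiguous blocks")
        starts = [b[0] for b in idx if b.size]
        if starts != sorted(starts):
            raise ValueError(f"phases must appear in order {PHASES}")

    def mask(self, *phases: str) -> np.ndarray:
        return np.isin(self.phase, phases)

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class ContactPoint:
    """Detected contact point: position offset and sample index."""

    offset: float  # m, position where the tip first touches the surface
    index: int
    baseline_sd: float  # N, noise level of the pre-contact force


@dataclass
class HertzFitResult:
    youngs_modulus: float  # Pa
    youngs_modulus_se: float  # Pa
    contact_point: float  # m, position offset applied before fitting
    fit_depth_max: float  # m
    residual_norm: float  # N
    n_points: int


@dataclass
class PLRFitResult:
    E1: float  # Pa (relaxation modulus at t = 1 s)
    alpha: float
    residual_norm: float  # N
    converged: bool
    n_points: int = 0


def hertz_force(E: float, depth: np.ndarray, tip_radius: float, nu: float = 0.5) -> np.ndarray:
    """Elastic spherical-contact force, F = (4/3) E/(1-nu^2) delta^(3/2) sqrt(R)."""
    delta = np.clip(np.asarray(depth, dtype=float), 0.0, None)
    return (4.0 / 3.0) * E / (1.0 - nu**2) * delta**1.5 * np.sqrt(tip_radius)


def closed_form_ramp_force(
    E1: float,
    alpha: float,
    speed: float,
    time: np.ndarray,
    tip_radius: float,
    nu: float = 0.5,
) -> np.ndarray:
    """Exact Ting force for constant-speed loading delta = v t of a PLR solid.

    The hereditary convolution of the power-law kernel with the power-law
    contact term evaluates to a Beta function:

        F(t) = [4 sqrt(R) / (3 (1-nu^2))] * E1 * v^(3/2) * (3/2)
               * B(3/2, 1 - alpha) * t^(3/2 - alpha).

    Serves as the independent oracle for the numerical forward model.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    t = np.asarray(time, dtype=float)
    pref = 4.0 * np.sqrt(tip_radius) / (3.0 * (1.0 - nu**2))
    return pref * E1 * speed**1.5 * 1.5 * beta_fn(1.5, 1.0 - alpha) * t ** (1.5 - alpha)


def _peak_index(depth: np.ndarray) -> int:
    """Last index at which the (single-peaked) depth attains its maximum."""
    dmax = depth.max()
    tol = 1e-12 * max(dmax, 1e-30)
    at_max = np.nonzero(depth >= dmax - tol)[0]
    i_m = int(at_max[-1])
    if np.any(np.diff(depth[: i_m + 1]) < -tol) or np.any(np.diff(depth[i_m:]) > tol):
        raise ValueError("depth history must be single-peaked (one load-dwell-retract cycle)")
    return i_m


def ting_forward(
    E1: float,
    alpha: float,
    time: np.ndarray,
    depth: np.ndarray,
    tip_radius: float,
    nu: float = 0.5,
    return_t1: bool = False,
):
    """Force history of a PLR half-space indented by a sphere (Ting's solution).

    ``depth`` is the indentation history (negative values are clipped to 0,
    i.e. out of contact); it must rise to a single peak/plateau and then
    descend.  Times are measured from the start of the record; the depth at
    ``time[0]`` should be 0 (contact).

    Returns the force array, and optionally the auxiliary-time array t1(t)
    (equal to t itself while the contact grows).

    The contact term delta^(3/2) has singular curvature where the tip
    touches down; besides the exact treatment of the onset interval, the
    few intervals following contact are internally subdivided (depth
    linearly interpolated) to keep the product quadrature uniformly
    accurate.  Forces are reported on the caller's grid.
    """
    t = np.asarray(time, dtype=float)
    d = np.clip(np.asarray(depth, dtype=float), 0.0, None)
    if t.ndim != 1 or t.shape != d.shape:
        raise ValueError("time and depth must be congruent 1-D arrays")
    onset = np.nonzero((d[:-1] <= 0.0) & (d[1:] > 0.0))[0]
    if onset.size:
        i0 = int(onset[0])
        t_r, d_r, keep = _refine_after_contact(t, d, i0, n_intervals=12, factor=16)
        res = _ting_forward_grid(E1, alpha, t_r, d_r, tip_radius, nu, return_t1)
        if return_t1:
            return res[0][keep], res[1][keep]
        return res[keep]
    return _ting_forward_grid(E1, alpha, t, d, tip_radius, nu, return_t1)


def _refine_after_contact(
    t: np.ndarray, d: np.ndarray, i0: int, n_intervals: int, factor: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subdivide intervals i0+1 .. i0+n_intervals by ``factor`` (linear depth)."""
    n = t.size
    hi = min(i0 + 1 + n_intervals, n - 1)
    pieces_t = [t[: i0 + 2]]
    pieces_d = [d[: i0 + 2]]
    keep_idx = list(range(i0 + 2))
    pos = i0 + 2 - 1  # index of last appended node in refined arrays
    for j in range(i0 + 1, hi):
        sub = np.linspace(t[j], t[j + 1], factor + 1)[1:]
        pieces_t.append(sub)
        pieces_d.append(d[j] + (d[j + 1] - d[j]) * (sub - t[j]) / (t[j + 1] - t[j]))
        pos += factor
        keep_idx.append(pos)
    if hi < n - 1:
        pieces_t.append(t[hi + 1 :])
        pieces_d.append(d[hi + 1 :])
        keep_idx.extend(range(pos + 1, pos + 1 + (n - 1 - hi)))
    return (
        np.concatenate(pieces_t),
        np.concatenate(pieces_d),
        np.asarray(keep_idx, dtype=int),
    )


def _ting_forward_grid(
    E1: float,
    alpha: float,
    t: np.ndarray,
    d: np.ndarray,
    tip_radius: float,
    nu: float = 0.5,
    return_t1: bool = False,
):
    if E1 <= 0:
        raise ValueError("E1 must be positive")
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    n = t.size
    om = 1.0 - alpha
    pref = 4.0 * np.sqrt(tip_radius) / (3.0 * (1.0 - nu**2))

    g = d**1.5
    dt = np.diff(t)
    slope_g = np.diff(g) / dt
    slope_d = np.diff(d) / dt

    i_m = _peak_index(d)

    # Contact-onset interval: depth leaves zero.  There g ~ (xi - t_ic)^(3/2)
    # (any smooth loading is locally a ramp), and a piecewise-linear rendering
    # of g would dominate the quadrature error, so the kernel is integrated
    # against that local power law exactly (incomplete Beta function).
    onset = np.nonzero((d[:-1] <= 0.0) & (d[1:] > 0.0))[0]
    ic = int(onset[0]) if onset.size else None

    def _onset_exact(T: np.ndarray, zmax: np.ndarray | float) -> np.ndarray:
        """∫_0^{min(zmax, h)} (T - z)^(-alpha) d[g1 (z/h)^(3/2)] for lags T > 0."""
        h = dt[ic]
        g1 = g[ic + 1]
        x = np.minimum(np.minimum(zmax, h), T) / T
        return g1 * h**-1.5 * 1.5 * T ** (1.5 - alpha) * betainc(1.5, om, x) * beta_fn(1.5, om)

    slope_g_pl = slope_g.copy()
    if ic is not None:
        slope_g_pl[ic] = 0.0  # handled exactly, not piecewise-linearly

    F = np.zeros(n)
    t1 = t.copy()

    # --- growing-contact part (load + dwell): full hereditary integral ---
    n_load = i_m + 1
    tt = t[:n_load, None]  # (n_load, 1)
    tl = t[None, : n_load - 1]
    tr = t[None, 1:n_load]
    valid = tr <= tt + 1e-18
    ka = np.where(valid, tt - tl, 0.0)
    kb = np.where(valid, np.maximum(tt - tr, 0.0), 0.0)
    K = (ka**om - kb**om) / om
    F[:n_load] = pref * E1 * (K * slope_g_pl[None, : n_load - 1] * valid).sum(axis=1)
    if ic is not None:
        rows = np.nonzero(t[:n_load] > t[ic])[0]
        if rows.size:
            F[rows] += pref * E1 * _onset_exact(t[rows] - t[ic], dt[ic])

    # --- retraction: truncate the integral at the auxiliary time t1(t) ---
    t1_prev = t[i_m]
    lost = False
    for nn in range(n_load, n):
        if lost:
            t1[nn] = 0.0
            continue
        tn = t[nn]
        a = t[:nn]
        b = t[1 : nn + 1]
        contrib = slope_d[:nn] * ((tn - a) ** om - (tn - b) ** om) / om
        # suffix sums: S[j] = Phi(t_j) = ∫_{t_j}^{t_n} kernel * depth-rate
        S = np.concatenate([np.cumsum(contrib[::-1])[::-1], [0.0]])
        if S[0] <= 0.0:
            # even integrating from 0 gives no tension balance: contact lost
            lost = True
            t1[nn] = 0.0
            continue
        pos = np.nonzero(S > 0.0)[0]
        j = int(pos[-1])
        if j >= nn:  # Phi positive everywhere (should not happen during retract)
            t1_n = t1_prev
        else:
            sl = slope_d[j]
            if sl <= 1e-300:
                t1_n = t[j + 1]
            else:
                rhs = (tn - t[j + 1]) ** om - om * S[j + 1] / sl
                t1_n = tn - rhs ** (1.0 / om)
        t1_n = float(np.clip(t1_n, t[j], min(t[j + 1], t1_prev)))
        t1_prev = t1_n
        t1[nn] = t1_n
        # force: integrate d(g)/dxi up to t1_n
        j2 = int(np.searchsorted(t, t1_n, side="right") - 1)
        j2 = min(j2, n - 2)
        val = 0.0
        if j2 > 0:
            af = t[:j2]
            bf = t[1 : j2 + 1]
            val += float(np.sum(slope_g_pl[:j2] * ((tn - af) ** om - (tn - bf) ** om) / om))
        if t1_n > t[j2]:
            sl_g = slope_g_pl[j2] if ic is None or j2 != ic else 0.0
            val += sl_g * ((tn - t[j2]) ** om - (tn - t1_n) ** om) / om
        if ic is not None and t1_n > t[ic]:
            val += float(_onset_exact(np.array([tn - t[ic]]), t1_n - t[ic])[0])
        F[nn] = max(pref * E1 * val, 0.0)

    if return_t1:
        return F, t1
    return F


def detect_contact_point(
    curve: IndentationCurve,
    min_baseline: int = 10,
    snr_threshold: float = 3.0,
    rise_exponents: tuple[float, ...] = (1.5, 1.45, 1.4, 1.35, 1.3, 1.25, 1.2),
) -> ContactPoint:
    """Locate the contact point on the loading sweep.

    Two-segment piecewise model over candidate split samples k: a flat
    force baseline before k, a contact rise ~ (position - position_k)^q
    after; the (k, q) pair minimizing the total squared error wins.  The
    exponent grid covers the Hertzian 3/2 power and the shallower ramp
    response of power-law-rheology samples (3/2 - alpha): with the exponent
    pinned at 3/2, the split point of a viscoelastic curve is biased early.
    Raises if the post-split rise is below ``snr_threshold`` times the
    baseline noise SD ("no contact") or if the record has no pre-contact
    baseline.
    """
    # approach + loading sweep only: stop at the first sample of peak depth
    # (during a dwell the force relaxes, which the rise model cannot follow)
    upto = int(np.argmax(curve.depth)) + 1
    p = curve.depth[:upto]
    F = curve.force[:upto]
    n = p.size
    if n < min_baseline + 5:
        raise ValueError("curve too short for contact detection")
    best = None
    for k in range(min_baseline, n - 4):
        b = F[:k].mean()
        base_sse = float(np.sum((F[:k] - b) ** 2))
        x = np.clip(p[k:] - p[k], 0.0, None)
        for q in rise_exponents:
            m = x**q
            mm = float(m @ m)
            a = max(float(m @ (F[k:] - b)) / mm, 0.0) if mm > 0 else 0.0
            sse = base_sse + float(np.sum((F[k:] - b - a * m) ** 2))
            if best is None or sse < best[0]:
                best = (sse, k, a, b, q)
    _, k, a, b, q = best
    baseline_sd = float(F[:k].std())
    rise = a * float(np.clip(p[-1] - p[k], 0.0, None) ** q)
    if rise < snr_threshold * max(baseline_sd, 1e-30):
        raise ValueError("no contact: force rise below noise level")
    if k <= min_baseline:
        # force already rising inside the minimal baseline: no flat region
        baseline_slope = np.polyfit(np.arange(k), F[:k], 1)[0]
        if abs(baseline_slope) * k > snr_threshold * max(baseline_sd, 1e-30):
            raise ValueError("no pre-contact baseline in record")
    return ContactPoint(offset=float(p[k]), index=int(k), baseline_sd=baseline_sd)


def fit_hertz(
    curve: IndentationCurve,
    fit_fraction: float = 0.1,
    contact: ContactPoint | float | None = None,
) -> HertzFitResult:
    """Hertzian Young's modulus from the shallow loading segment.

    Fits F = (4/3) E/(1-nu^2) delta^(3/2) sqrt(R) over indentation depths
    0 < delta <= fit_fraction * R (default 900 nm for a 9-µm tip).  The
    loading segment must span that depth range.  E enters linearly, so the
    fit is an exact linear least squares through the origin.
    """
    offset = 0.0
    if isinstance(contact, ContactPoint):
        offset = contact.offset
    elif contact is not None:
        offset = float(contact)
    upto = _peak_index(np.clip(curve.depth - offset, 0.0, None)) + 1
    delta = curve.depth[:upto] - offset
    F = curve.force[:upto]
    dmax_fit = fit_fraction * curve.tip_radius
    if delta.max() < dmax_fit:
        raise ValueError(
            f"loading spans {delta.max():.3g} m < required {dmax_fit:.3g} m "
            f"({fit_fraction:.0%} of tip radius)"
        )
    sel = (delta > 0) & (delta <= dmax_fit)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 samples inside the Hertz fit window")
    m = (4.0 / 3.0) / (1.0 - curve.nu**2) * np.sqrt(curve.tip_radius) * delta[sel] ** 1.5
    y = F[sel]
    mm = float(m @ m)
    E = float(m @ y) / mm
    resid = y - E * m
    nfit = int(sel.sum())
    var = float(resid @ resid) / max(nfit - 1, 1)
    se = float(np.sqrt(var / mm))
    return HertzFitResult(
        youngs_modulus=E,
        youngs_modulus_se=se,
        contact_point=offset,
        fit_depth_max=dmax_fit,
        residual_norm=float(np.linalg.norm(resid)),
        n_points=nfit,
    )


def fit_plr(
    curve: IndentationCurve,
    contact: ContactPoint | float | None = None,
    alpha_starts: tuple[float, ...] = (0.05, 0.2, 0.4),
    alpha_max: float = 0.95,
) -> PLRFitResult:
    """Invert the full load–dwell–retract cycle for (E1, alpha).

    Least squares on force residuals of the Ting forward model over the
    complete post-contact record, multi-started over alpha.  E1 is
    initialized per start by linear projection onto the unit-modulus forward
    force.  All three phases must be present.
    """
    for needed in ("load", "dwell", "retract"):
        if not np.any(curve.phase == needed):
            raise ValueError(f"curve lacks a {needed} phase")
    offset = 0.0
    i0 = 0
    if isinstance(contact, ContactPoint):
        offset, i0 = contact.offset, contact.index
    elif contact is not None:
        offset = float(contact)
        peak = _peak_index(np.clip(curve.depth, curve.depth.min(), None))
        i0 = int(np.searchsorted(curve.depth[: peak + 1], offset))
    t = curve.time[i0:] - curve.time[i0]
    d = np.clip(curve.depth[i0:] - offset, 0.0, None)
    F = curve.force[i0:]
    R, nu = curve.tip_radius, curve.nu

    f_scale = float(np.max(np.abs(F)))
    if f_scale <= 0:
        raise ValueError("curve has no measurable force")

    # residuals normalized by the peak force so the optimizer's tolerances
    # are meaningful regardless of the (nano-newton) force magnitude
    def resid(x: np.ndarray) -> np.ndarray:
        return (ting_forward(x[0], x[1], t, d, R, nu) - F) / f_scale

    best = None
    for a0 in alpha_starts:
        F1 = ting_forward(1.0, a0, t, d, R, nu)
        denom = float(F1 @ F1)
        e0 = max(float(F1 @ F) / denom, 1.0) if denom > 0 else 1e3
        try:
            res = least_squares(
                resid,
                x0=[e0, a0],
                bounds=([1e-3, 0.0], [1e9, alpha_max]),
                x_scale=[max(e0, 1.0), 0.1],
                diff_step=[1e-4, 1e-3],
                method="trf",
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return PLRFitResult(E1=np.nan, alpha=np.nan, residual_norm=np.inf, converged=False)
    return PLRFitResult(
        E1=float(best.x[0]),
        alpha=float(best.x[1]),
        residual_norm=float(np.sqrt(2.0 * best.cost)) * f_scale,
        converged=True,
        n_points=int(t.size),
    )


def summarize_sample(
    results: list,
    spheroid_ids: list | None = None,
) -> dict[str, dict[str, float]]:
    """Mean ± SD of the fitted parameters over replicate indentations.

    Accepts Hertz or PLR fit results (flagged PLR fits are dropped).  When
    ``spheroid_ids`` is given, replicates are first averaged within each
    spheroid (3–4 indents per spheroid is typical) and the SD is taken
    across spheroids.
    """
    keep: list = []
    ids: list = []
    for i, r in enumerate(results):
        if isinstance(r, PLRFitResult) and not r.converged:
            continue
        keep.append(r)
        ids.append(spheroid_ids[i] if spheroid_ids is not None else i)
    if len(keep) < 2:
        raise ValueError("need at least 2 unflagged results")
    if isinstance(keep[0], HertzFitResult):
        params = {"youngs_modulus": [r.youngs_modulus for r in keep]}
    else:
        params = {"E1": [r.E1 for r in keep], "alpha": [r.alpha for r in keep]}
    out: dict[str, dict[str, float]] = {}
    uniq = sorted(set(ids), key=str)
    for name, vals in params.items():
        vals = np.asarray(vals, dtype=float)
        if spheroid_ids is not None and len(uniq) > 1:
            per = np.array([vals[[i for i, s in enumerate(ids) if s == u]].mean() for u in uniq])
        else:
            per = vals
        sd = float(per.std(ddof=1)) if per.size > 1 else 0.0
        out[name] = {"mean": float(per.mean()), "sd": sd, "n": int(per.size)}
    return out
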