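"""Forward simulators for fusion trajectories, doublet image stacks and
indentation cycles.

These generators carry the statistical structure the downstream analysis
assumes — coalescence-law neck growth with multiplicative measurement
noise, rigid two-disk doublet silhouettes, and Ting/PLR force responses
with additive force noise — so every stage of the pipeline is testable
without recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .fusion import PLATEAU, NeckSeries
from .geometry import center_distance_for_neck
from .indentation import IndentationCurve, ting_forward

__all__ = [
    "DEFAULT_TIME_GRID_H",
    "FusionSimConfig",
    "IndentSimConfig",
    "CohortSpec",
    "simulate_fusion_series",
    "render_fusion_frames",
    "simulate_indentation_curve",
    "generate_cohort",
]

#: default fusion sampling schedule (h): 9 time points over 48 h.
DEFAULT_TIME_GRID_H: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 7.0, 24.0, 48.0)

#: spheroid radii never shrink below this fraction of their initial value.
_MIN_SHRINK = 0.1


@dataclass
class FusionSimConfig:
    """Ground truth for one simulated fusion pair."""

    tau: float  # h, coalescence time constant
    radius_a: float  # µm, initial radius of spheroid A
    radius_b: float  # µm
    time_points: Sequence[float] = DEFAULT_TIME_GRID_H  # h
    noise_cv: float = 0.05  # multiplicative CV on the neck radius
    compaction_rate: float = 0.0  # 1/h fractional radius shrinkage
    seed: int = 0
    pair_type: str = "synthetic"
    age_days: float = 7.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.radius_a <= 0 or self.radius_b <= 0:
            raise ValueError("radii must be positive")
        t = np.asarray(self.time_points, dtype=float)
        if t.size < 1 or t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time_points must be strictly increasing and start >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.compaction_rate < 0:
            raise ValueError("compaction_rate must be non-negative")


@dataclass
class IndentSimConfig:
    """Ground truth for one simulated indentation cycle (SI units).

    Defaults follow the experimental protocol: 9-µm spherical tip, 3.5-µm
    peak depth, 1-s dwell, incompressible sample (nu = 0.5).  The loading
    speed of 3.5 µm/s (a 1-s loading ramp) and the sampling rate are
    instrument-typical choices; ``approach_distance`` > 0 prepends a
    pre-contact baseline segment for contact-point detection.
    """

    E1: float = 1630.0  # Pa s^alpha, relaxation modulus at 1 s
    alpha: float = 0.16
    tip_radius: float = 9e-6  # m
    max_depth: float = 3.5e-6  # m
    approach_speed: float = 3.5e-6  # m/s
    dwell_time: float = 1.0  # s
    retract_speed: float = 3.5e-6  # m/s
    nu: float = 0.5
    force_noise_sd: float = 0.0  # N, additive Gaussian
    seed: int = 0
    approach_distance: float = 0.0  # m of pre-contact travel (baseline)
    sample_rate_hz: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.E1 <= 0:
            raise ValueError("E1 must be positive")
        if self.max_depth > 0.5 * self.tip_radius:
            raise ValueError("max_depth must not exceed half the tip radius")
        if self.max_depth <= 0 or self.tip_radius <= 0:
            raise ValueError("max_depth and tip_radius must be positive")
        if self.dwell_time < 0:
            raise ValueError("dwell_time must be non-negative")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must be in [0, 0.5]")
        if self.approach_speed <= 0 or self.retract_speed <= 0:
            raise ValueError("speeds must be positive")
        if self.force_noise_sd < 0 or self.approach_distance < 0:
            raise ValueError("force_noise_sd and approach_distance must be non-negative")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")


@dataclass
class CohortSpec:
    """A group of fusion pairs sharing one ground-truth visco-capillary velocity.

    Per-pair initial radii R0 are drawn from N(radius_mean, radius_sd)
    truncated to positive values, and each pair's tau follows from the
    droplet relation tau = 2^(2/3) R0 / (Gamma/eta).
    """

    visco_capillary_velocity: float  # µm/h, common ground-truth Gamma/eta
    n_pairs: int = 12
    radius_mean: float = 75.0  # µm (measured pairs spanned ~30-120 µm)
    radius_sd: float = 20.0  # µm
    group_label: str = "synthetic"
    ground_truth: FusionSimConfig = field(
        default_factory=lambda: FusionSimConfig(tau=10.0, radius_a=75.0, radius_b=75.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.radius_sd < 0:
            raise ValueError("radius_sd must be non-negative")
        if self.visco_capillary_velocity <= 0:
            raise ValueError("visco_capillary_velocity must be positive")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")


def simulate_fusion_series(config: FusionSimConfig) -> NeckSeries:
    """Simulate one neck-radius trajectory under the coalescence law.

    r0(t) = R0(t) * sqrt(2^(2/3) (1 - exp(-t/tau))) with R0(t) the mean of
    the two (optionally compacting) radii, then perturbed by mean-preserving
    lognormal noise of the configured CV.  The stored pair R0 is the initial
    average radius, matching how measured series are normalized.
    """
    t = np.asarray(config.time_points, dtype=float)
    rng = np.random.default_rng(config.seed)
    shrink = np.maximum(1.0 - config.compaction_rate * t, _MIN_SHRINK)
    ra = config.radius_a * shrink
    rb = config.radius_b * shrink
    y = PLATEAU * (1.0 - np.exp(-t / config.tau))
    r0 = 0.5 * (ra + rb) * np.sqrt(y)
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        r0 = r0 * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.size)
    return NeckSeries(
        times=t,
        neck_radius=r0,
        R0=0.5 * (config.radius_a + config.radius_b),
        radius_a=ra,
        radius_b=rb,
        pair_type=config.pair_type,
        age_days=config.age_days,
        meta={"tau_true": config.tau, "seed": config.seed, "noise_cv": config.noise_cv},
    )


def render_fusion_frames(
    series: NeckSeries,
    pixel_size: float,
    image_shape: tuple[int, int] = (256, 256),
    axis_angle: float = 0.0,
    foreground: int = 40,
    background: int = 220,
) -> np.ndarray:
    """Rasterize a fusing pair as an 8-bit image stack (dark disks on light).

    Each frame is the union of two disks whose center distance reproduces
    the frame's neck radius through the circle–circle chord relation.  The
    doublet axis passes through the frame center at ``axis_angle`` radians.
    Raises if any frame's neck exceeds the smaller lobe radius (no two-disk
    silhouette) or the doublet does not fit the frame.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if series.radius_a is None or series.radius_b is None:
        raise ValueError("series must carry per-frame lobe radii for rendering")
    h, w = image_shape
    stack = np.full((len(series), h, w), background, dtype=np.uint8)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    ux, uy = math.cos(axis_angle), math.sin(axis_angle)
    for k in range(len(series)):
        ra = series.radius_a[k] / pixel_size
        rb = series.radius_b[k] / pixel_size
        r0 = series.neck_radius[k] / pixel_size
        if np.isnan(r0):
            raise ValueError(f"frame {k}: missing neck radius")
        if r0 > min(ra, rb) * (1.0 + 1e-9):
            raise ValueError(
                f"frame {k}: neck radius {r0:.2f} px exceeds smaller lobe radius "
                f"{min(ra, rb):.2f} px"
            )
        d = center_distance_for_neck(ra, rb, min(r0, min(ra, rb)))
        # place centers so the neck plane sits at the frame center
        xa_off = math.sqrt(max(ra * ra - min(r0, ra) ** 2, 0.0))
        cax, cay = cx - xa_off * ux, cy - xa_off * uy
        cbx, cby = cx + (d - xa_off) * ux, cy + (d - xa_off) * uy
        for (ccx, ccy, r) in ((cax, cay, ra), (cbx, cby, rb)):
            if ccx - r < 0 or ccx + r > w - 1 or ccy - r < 0 or ccy + r > h - 1:
                raise ValueError(
                    f"frame {k}: doublet does not fit a {h}x{w} frame at "
                    f"{pixel_size} µm/px"
                )
        mask = ((xx - cax) ** 2 + (yy - cay) ** 2 <= ra * ra) | (
            (xx - cbx) ** 2 + (yy - cby) ** 2 <= rb * rb
        )
        stack[k][mask] = foreground
    return stack


def simulate_indentation_curve(config: IndentSimConfig) -> IndentationCurve:
    """Simulate one load–dwell–retract cycle of a PLR sample.

    The depth command is a triangle with plateau (ramp to ``max_depth`` at
    ``approach_speed``, hold ``dwell_time``, ramp down at ``retract_speed``),
    optionally preceded by a pre-contact approach.  The force follows Ting's
    solution for the configured (E1, alpha); additive Gaussian force noise
    is applied last.
    """
    dt = 1.0 / config.sample_rate_hz
    t_app = config.approach_distance / config.approach_speed
    t_load = config.max_depth / config.approach_speed
    t_ret = config.max_depth / config.retract_speed
    n_app = int(round(t_app / dt))
    n_load = max(int(round(t_load / dt)), 2)
    n_dwell = int(round(config.dwell_time / dt))
    n_ret = max(int(round(t_ret / dt)), 2)
    n = n_app + n_load + n_dwell + n_ret + 1
    time = np.arange(n) * dt
    depth = np.empty(n)
    phase = np.empty(n, dtype=object)
    i = 0
    depth[:n_app] = -config.approach_distance + config.approach_speed * time[:n_app]
    phase[:n_app] = "approach"
    i += n_app
    t0 = time[i] if n_app else 0.0
    depth[i : i + n_load] = config.approach_speed * (time[i : i + n_load] - t0)
    phase[i : i + n_load] = "load"
    i += n_load
    depth[i : i + n_dwell] = config.max_depth
    phase[i : i + n_dwell] = "dwell"
    i += n_dwell
    t1 = time[i]
    depth[i - 1] = config.max_depth  # pin the peak sample exactly
    depth[i:] = config.max_depth - config.retract_speed * (time[i:] - t1)
    phase[i:] = "retract"
    depth = np.where(np.abs(depth) < 1e-18, 0.0, depth)

    contact = np.clip(depth, 0.0, None)
    force = ting_forward(config.E1, config.alpha, time, contact, config.tip_radius, config.nu)
    if config.force_noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        force = force + rng.normal(0.0, config.force_noise_sd, size=n)
    return IndentationCurve(
        time=time,
        depth=depth,
        force=force,
        phase=phase.astype(str),
        tip_radius=config.tip_radius,
        nu=config.nu,
        meta={
            "E1_true": config.E1,
            "alpha_true": config.alpha,
            "seed": config.seed,
            "contact_index": n_app,
            "force_noise_sd": config.force_noise_sd,
        },
    )


def generate_cohort(spec: CohortSpec) -> list[NeckSeries]:
    """Generate ``n_pairs`` fusion series with a common ground-truth Gamma/eta.

    Per-pair R0 ~ N(radius_mean, radius_sd) truncated positive; per-pair
    tau = 2^(2/3) R0 / (Gamma/eta).  Per-pair seeds derive from the master
    seed through a spawned counter-based sequence, so cohorts are
    reproducible element-wise.
    """
    master = np.random.SeedSequence(spec.seed)
    radius_ss, *pair_ss = master.spawn(spec.n_pairs + 1)
    rng = np.random.default_rng(radius_ss)
    radii = np.empty(spec.n_pairs)
    for i in range(spec.n_pairs):
        r = rng.normal(spec.radius_mean, spec.radius_sd) if spec.radius_sd > 0 else spec.radius_mean
        while r <= 0:
            r = rng.normal(spec.radius_mean, spec.radius_sd)
        radii[i] = r
    out = []
    for i, (r, ss) in enumerate(zip(radii, pair_ss)):
        tau_i = PLATEAU * r / spec.visco_capillary_velocity
        cfg = replace(
            spec.ground_truth,
            tau=float(tau_i),
            radius_a=float(r),
            radius_b=float(r),
            seed=int(ss.generate_state(1, np.uint32)[0] % (2**31)),
            pair_type=spec.group_label,
        )
        out.append(simulate_fusion_series(cfg))
    return out
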