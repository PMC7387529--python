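import numpy as np
import pytest

from spheromech.fusion import PLATEAU, fit_liquid_drop
from spheromech.indentation import closed_form_ramp_force, hertz_force
from spheromech.synthetic import (
    DEFAULT_TIME_GRID_H,
    CohortSpec,
    FusionSimConfig,
    IndentSimConfig,
    generate_cohort,
    render_fusion_frames,
    simulate_fusion_series,
    simulate_indentation_curve,
)


class TestFusionSeries:
    def test_neck_zero_at_time_zero(self):
        cfg = FusionSimConfig(tau=10.0, radius_a=100.0, radius_b=100.0,
                              time_points=[0.0, 1.0], noise_cv=0.0)
        s = simulate_fusion_series(cfg)
        assert s.neck_radius[0] == 0.0

    def test_plateau_at_late_times(self):
        cfg = FusionSimConfig(tau=10.0, radius_a=100.0, radius_b=100.0,
                              time_points=[1e4], noise_cv=0.0)
        s = simulate_fusion_series(cfg)
        assert (s.neck_radius[0] / s.R0) ** 2 == pytest.approx(2 ** (2 / 3), rel=1e-9)

    def test_value_at_one_time_constant(self):
        # (r0/R0)^2 = 2^(2/3) (1 - 1/e) = 1.0035 at t = tau
        cfg = FusionSimConfig(tau=10.0, radius_a=100.0, radius_b=100.0,
                              time_points=[10.0], noise_cv=0.0)
        s = simulate_fusion_series(cfg)
        assert (s.neck_radius[0] / s.R0) ** 2 == pytest.approx(1.0035, abs=2e-4)

    def test_default_grid_is_nine_points_over_48h(self):
        s = simulate_fusion_series(FusionSimConfig(tau=10.0, radius_a=80.0, radius_b=80.0))
        assert len(s) == 9
        assert s.times[0] == 0.5 and s.times[-1] == 48.0

    def test_reproducible_under_fixed_seed(self):
        cfg = FusionSimConfig(tau=10.0, radius_a=90.0, radius_b=70.0, noise_cv=0.1, seed=5)
        a = simulate_fusion_series(cfg)
        b = simulate_fusion_series(cfg)
        np.testing.assert_array_equal(a.neck_radius, b.neck_radius)

    def test_lognormal_noise_cv_matches_request(self):
        cfg = FusionSimConfig(tau=10.0, radius_a=100.0, radius_b=100.0,
                              time_points=[20.0], noise_cv=0.1)
        vals = []
        for seed in range(2000):
            s = simulate_fusion_series(
                FusionSimConfig(tau=10.0, radius_a=100.0, radius_b=100.0,
                                time_points=[20.0], noise_cv=0.1, seed=seed)
            )
            vals.append(s.neck_radius[0])
        vals = np.asarray(vals)
        assert vals.std() / vals.mean() == pytest.approx(0.1, rel=0.1)
        # mean-preserving noise
        clean = simulate_fusion_series(cfg.__class__(**{**cfg.__dict__, "noise_cv": 0.0}))
        assert vals.mean() == pytest.approx(clean.neck_radius[0], rel=0.01)

    def test_compaction_shrinks_radii_with_floor(self):
        cfg = FusionSimConfig(tau=10.0, radius_a=100.0, radius_b=100.0,
                              time_points=[0.0, 10.0, 1000.0], noise_cv=0.0,
                              compaction_rate=0.02)
        s = simulate_fusion_series(cfg)
        assert s.radius_a[1] == pytest.approx(80.0)
        assert s.radius_a[2] == pytest.approx(10.0)  # clamped at 10% of initial

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            FusionSimConfig(tau=10.0, radius_a=100.0, radius_b=100.0,
                            time_points=[1.0, 1.0, 2.0])


class TestCohort:
    def test_deterministic_under_master_seed(self):
        spec = CohortSpec(visco_capillary_velocity=8.4, n_pairs=12, seed=3)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.neck_radius, sb.neck_radius)
            assert sa.R0 == sb.R0

    def test_zero_radius_spread_gives_common_tau(self):
        spec = CohortSpec(visco_capillary_velocity=8.4, n_pairs=5, radius_sd=0.0,
                          radius_mean=100.0, seed=1)
        taus = {s.meta["tau_true"] for s in generate_cohort(spec)}
        assert len(taus) == 1
        # tau = 2^(2/3) * 100 / 8.4 = 18.9 h
        assert taus.pop() == pytest.approx(18.898, abs=1e-3)

    def test_tau_follows_droplet_relation_per_pair(self):
        spec = CohortSpec(visco_capillary_velocity=5.0, n_pairs=8, radius_sd=25.0, seed=2)
        for s in generate_cohort(spec):
            assert s.meta["tau_true"] == pytest.approx(PLATEAU * s.R0 / 5.0)


class TestRenderer:
    def _series(self, r0, ra=100.0, rb=100.0):
        from spheromech.fusion import NeckSeries
        return NeckSeries(times=[0.0], neck_radius=[r0], R0=(ra + rb) / 2,
                          radius_a=np.array([ra]), radius_b=np.array([rb]))

    def test_zero_neck_renders_tangent_disks(self):
        stack = render_fusion_frames(self._series(0.0, 80.0, 60.0), 2.0, (256, 256))
        assert stack.shape == (1, 256, 256)
        assert set(np.unique(stack[0])) == {40, 220}

    def test_full_coalescence_single_disk(self):
        stack = render_fusion_frames(self._series(80.0, 80.0, 80.0), 2.0, (256, 256))
        area = (stack[0] == 40).sum()
        assert area == pytest.approx(np.pi * 40.0**2, rel=0.02)  # one 40-px disk

    def test_neck_exceeding_lobe_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            render_fusion_frames(self._series(70.0, 100.0, 60.0), 2.0, (256, 256))

    def test_doublet_must_fit_frame(self):
        with pytest.raises(ValueError, match="does not fit"):
            render_fusion_frames(self._series(20.0, 100.0, 100.0), 1.0, (128, 128))

    def test_frame_count_matches_time_points(self):
        cfg = FusionSimConfig(tau=30.0, radius_a=80.0, radius_b=80.0, noise_cv=0.0,
                              time_points=[0.5, 1.0, 2.0, 3.0])
        s = simulate_fusion_series(cfg)
        stack = render_fusion_frames(s, 2.0, (256, 256))
        assert stack.shape[0] == 4


class TestIndentationSim:
    def test_elastic_peak_force_matches_hertz(self):
        # E = 3940 Pa, nu = 0.5, R = 9 µm, delta = 3.5 µm -> F = 137.6 nN
        c = simulate_indentation_curve(IndentSimConfig(E1=3940.0, alpha=0.0))
        peak = c.force[np.argmax(c.depth)]
        assert peak == pytest.approx(137.6e-9, rel=1e-3)

    def test_dwell_force_relaxes_for_viscoelastic_sample(self):
        c = simulate_indentation_curve(IndentSimConfig(E1=2000.0, alpha=0.15))
        dwell = c.force[c.phase == "dwell"]
        assert np.all(np.diff(dwell) < 0)

    def test_ramp_phase_matches_beta_function_closed_form(self):
        cfg = IndentSimConfig(E1=2500.0, alpha=0.15)
        c = simulate_indentation_curve(cfg)
        load = c.phase == "load"
        t = c.time[load]
        ref = closed_form_ramp_force(cfg.E1, cfg.alpha, cfg.approach_speed, t,
                                     cfg.tip_radius, cfg.nu)
        sel = ref > 0
        rel = np.abs(c.force[load][sel] - ref[sel]) / ref[sel]
        assert rel.max() < 1e-3

    def test_elastic_curve_tracks_hertz_pointwise(self):
        cfg = IndentSimConfig(E1=3000.0, alpha=0.0)
        c = simulate_indentation_curve(cfg)
        ref = hertz_force(cfg.E1, c.depth, cfg.tip_radius, cfg.nu)
        assert np.abs(c.force - ref).max() / ref.max() < 1e-3

    def test_phase_labels_and_baseline(self):
        c = simulate_indentation_curve(IndentSimConfig(approach_distance=1e-6))
        assert list(dict.fromkeys(c.phase)) == ["approach", "load", "dwell", "retract"]
        assert np.all(c.depth[c.phase == "approach"] < 0)
        assert np.all(c.force[c.phase == "approach"] == 0.0)

    def test_force_noise_reproducible(self):
        cfg = IndentSimConfig(force_noise_sd=1e-9, seed=11)
        a = simulate_indentation_curve(cfg)
        b = simulate_indentation_curve(cfg)
        np.testing.assert_array_equal(a.force, b.force)

    def test_depth_cap_invariant(self):
        with pytest.raises(ValueError):
            IndentSimConfig(max_depth=5e-6, tip_radius=9e-6)
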