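"""Synthetic task generators: determinism, ground truth, recovery."""

import numpy as np
import pytest

from movelements import decompose as dec
from movelements import minjerk as mj
from movelements import preprocess as pp
from movelements import scaling as sc
from movelements import synthetic as syn


def _segment_axis(recording, axis):
    return dec.segment(pp.differentiate(recording), axis)


class TestGenElement:
    def test_duration_follows_duration_law(self):
        res = syn.gen_element(100.0, 1e-9, 100.0)
        t_f = res.ground_truth.iloc[0].t_f
        assert t_f == pytest.approx((60.0 * 100.0) ** (1 / 3) * 1e-9 ** (1 / 6), rel=1e-12)

    def test_net_displacement_exact(self):
        res = syn.gen_element(100.0, 1e-9, 100.0)
        x = res.recording.axes["x"]
        assert x[-1] - x[0] == pytest.approx(100.0, abs=1e-12)

    def test_decomposes_to_one_non_boundary_element(self):
        res = syn.gen_element(-80.0, 1e-9, 100.0)
        els = _segment_axis(res.recording, "x")
        assert len(els) == 1
        assert not els[0].boundary_flag
        assert els[0].sign == -1

    def test_resolution_guard(self):
        # K = 1e-18 gives t_f ~ 18 ms: fewer than 5 samples at 100 Hz
        with pytest.raises(syn.ResolutionError):
            syn.gen_element(100.0, 1e-18, 100.0)

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_element(0.0, 1e-9)


class TestSequence1D:
    def test_recovers_generating_displacements(self):
        res = syn.gen_sequence_1d([100.0, -50.0, 75.0], K=1e-9)
        els = [e for e in _segment_axis(res.recording, "x") if abs(e.D) > 1.0]
        assert len(els) == 3
        for el, d in zip(els, [100.0, -50.0, 75.0]):
            assert el.D == pytest.approx(d, abs=1.0)

    def test_ruler_displacements_land_on_ruler_marks(self):
        d = syn.ruler_displacements(45, seed=4)
        assert d.shape == (45,)
        assert np.all(d % 25.0 == 0)
        assert np.all(d != 0)
        assert np.all(np.abs(d) <= 59 * 25.0)

    def test_seed_determinism(self):
        a = syn.gen_sequence_1d(seed=9)
        b = syn.gen_sequence_1d(seed=9)
        assert np.array_equal(a.recording.axes["x"], b.recording.axes["x"])
        assert a.ground_truth.equals(b.ground_truth)

    def test_scaling_exponent_near_two_thirds(self):
        res = syn.gen_sequence_1d(seed=2)
        kept, _ = dec.apply_filters(
            _segment_axis(res.recording, "x"), dec.task_criteria("movement_1d")
        )
        fit = sc.fit_scaling(kept)
        assert fit.alpha == pytest.approx(2.0 / 3.0, abs=0.02)


class TestSequence1DNoTargets:
    def test_element_displacement_is_speed_times_interval(self):
        res = syn.gen_sequence_1d_no_targets(
            150.0, reversal_times=[1.0, 2.0, 3.0], speed_jitter=0.0
        )
        els = [e for e in _segment_axis(res.recording, "x") if not e.boundary_flag]
        for e in els:
            assert abs(e.D) == pytest.approx(150.0, rel=0.02)

    def test_mean_speed_decoupled_from_displacement(self):
        res = syn.gen_sequence_1d_no_targets(150.0, seed=3)
        kept, _ = dec.apply_filters(
            _segment_axis(res.recording, "x"), dec.task_criteria("movement_1d")
        )
        fit = sc.fit_scaling(kept)
        assert abs(fit.pearson_r) < 0.3
        assert abs(fit.alpha) < 0.15

    def test_seed_determinism(self):
        a = syn.gen_sequence_1d_no_targets(seed=5)
        b = syn.gen_sequence_1d_no_targets(seed=5)
        assert np.array_equal(a.recording.axes["x"], b.recording.axes["x"])

    def test_non_increasing_reversals_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_sequence_1d_no_targets(150.0, reversal_times=[1.0, 0.9, 2.0])

    def test_too_few_reversals_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_sequence_1d_no_targets(150.0, reversal_times=[1.0, 2.0])


class TestEllipse:
    def test_one_repetition_two_x_elements(self):
        res = syn.gen_ellipse(120.0, 60.0, n_reps=1, K=1e-9, pad_s=0.3)
        els = [
            e for e in _segment_axis(res.recording, "x")
            if not e.boundary_flag and abs(e.D) > 1.0
        ]
        assert len(els) == 2
        assert {e.sign for e in els} == {-1, 1}
        for e in els:
            assert abs(e.D) == pytest.approx(240.0, rel=0.01)

    def test_x_scaling_across_sizes(self):
        kept = []
        for major in (15.0, 30.0, 60.0, 120.0, 240.0):
            res = syn.gen_ellipse(major / 2, major / 4, n_reps=2, K=1e-9, pad_s=0.3)
            k, _ = dec.apply_filters(
                _segment_axis(res.recording, "x"), dec.task_criteria("drawing")
            )
            kept.extend(k)
        fit = sc.fit_scaling(kept)
        assert fit.alpha == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_composition_mode_elements_match_profile(self):
        res = syn.gen_ellipse(
            60.0, 30.0, n_reps=2, K=1e-9, mode="minjerk_composition", pad_s=0.3
        )
        kept, _ = dec.apply_filters(
            _segment_axis(res.recording, "x"), dec.task_criteria("drawing")
        )
        assert kept
        # junction samples mix the two adjacent arches through the central-
        # difference window, so the fit is near- but not machine-perfect
        for e in kept:
            assert mj.fit_element(e) > 0.99

    def test_invalid_geometry_and_mode_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_ellipse(10.0, 20.0)
        with pytest.raises(ValueError):
            syn.gen_ellipse(20.0, 10.0, mode="spline")


class TestPureFrequency:
    def test_nu_zero_epsilon_zero_is_constant_speed_circle(self):
        from movelements import curvature as cv

        res = syn.gen_pure_frequency(0.0, 0.0, size=120.0, K=1e-9)
        series = cv.compute_curvature(res.recording)
        m = series.valid_mask
        # constant radius of curvature and constant speed
        assert np.std(series.radius[m]) / np.mean(series.radius[m]) < 0.01
        assert np.std(series.speed[m]) / np.mean(series.speed[m]) < 0.01

    @pytest.mark.parametrize("nu,eps", [(0.8, 1.0), (4.0 / 3.0, 0.8), (3.0, 1.2)])
    def test_one_third_law_imposed_by_tracing_rule(self, nu, eps):
        from movelements import curvature as cv

        res = syn.gen_pure_frequency(eps, nu, size=120.0, K=1e-9)
        fit = cv.fit_speed_curvature_law(cv.compute_curvature(res.recording))
        assert fit.exponent == pytest.approx(1.0 / 3.0, abs=5e-3)

    def test_requested_width_honoured(self):
        res = syn.gen_pure_frequency(0.9, 0.8, size=60.0, K=1e-9)
        assert np.ptp(res.recording.axes["x"]) == pytest.approx(60.0, rel=0.01)


class TestRandom3D:
    def test_three_axes_with_ground_truth(self):
        res = syn.gen_random_3d(5, (20.0, 200.0), 1e-9, seed=1)
        assert set(res.recording.axes) == {"x", "y", "z"}
        assert len(res.ground_truth) == 15

    def test_single_element_per_axis(self):
        res = syn.gen_random_3d(1, (50.0, 100.0), 1e-9, seed=2)
        total = sum(
            len([e for e in _segment_axis(res.recording, ax) if abs(e.D) > 1.0])
            for ax in "xyz"
        )
        assert total == 3

    def test_seed_determinism(self):
        a = syn.gen_random_3d(8, (20.0, 200.0), 1e-9, seed=7)
        b = syn.gen_random_3d(8, (20.0, 200.0), 1e-9, seed=7)
        for ax in "xyz":
            assert np.array_equal(a.recording.axes[ax], b.recording.axes[ax])

    def test_recovery_of_displacement_and_duration(self):
        res = syn.gen_random_3d(20, (40.0, 300.0), 1e-9, seed=5)
        kept, _ = dec.apply_filters(
            [e for ax in "xyz" for e in _segment_axis(res.recording, ax)],
            dec.task_criteria("movement_3d"),
        )
        matched = 0
        for _, row in res.ground_truth.iterrows():
            cand = [
                e for e in kept
                if e.axis == row.axis and abs(e.t_start - row.t_start) < 0.15
            ]
            if not cand:
                continue
            e = max(cand, key=lambda q: abs(q.D))
            matched += 1
            assert abs(e.D) == pytest.approx(abs(row.D), rel=0.01)
            assert e.t_f == pytest.approx(row.t_f, rel=0.02)
        assert matched >= 0.9 * len(res.ground_truth)

    def test_alpha_recovered_within_five_hundredths(self):
        res = syn.gen_random_3d(20, (20.0, 200.0), 1e-9, seed=3)
        kept, _ = dec.apply_filters(
            [e for ax in "xyz" for e in _segment_axis(res.recording, ax)],
            dec.task_criteria("movement_3d"),
        )
        fit = sc.fit_scaling(kept)
        assert fit.alpha == pytest.approx(2.0 / 3.0, abs=0.05)


class TestAddNoise:
    def test_zero_sd_is_identity(self):
        res = syn.gen_element(100.0, 1e-9)
        noisy = syn.add_noise(res.recording, 0.0, seed=1)
        assert np.array_equal(noisy.axes["x"], res.recording.axes["x"])

    def test_seed_determinism_and_scale(self):
        res = syn.gen_element(100.0, 1e-9)
        n1 = syn.add_noise(res.recording, 0.5, seed=3)
        n2 = syn.add_noise(res.recording, 0.5, seed=3)
        n3 = syn.add_noise(res.recording, 0.5, seed=4)
        assert np.array_equal(n1.axes["x"], n2.axes["x"])
        assert not np.array_equal(n1.axes["x"], n3.axes["x"])
        resid = n1.axes["x"] - res.recording.axes["x"]
        assert np.std(resid) == pytest.approx(0.5, rel=0.15)

    def test_negative_sd_rejected(self):
        res = syn.gen_element(100.0, 1e-9)
        with pytest.raises(ValueError):
            syn.add_noise(res.recording, -0.1)


class TestSpecDispatch:
    def test_round_trip_and_generate(self):
        spec = syn.SyntheticSpec(
            scenario="ellipse",
            params={"a": 60.0, "b": 30.0, "n_reps": 1, "K": 1e-9},
            seed=7,
        )
        restored = syn.SyntheticSpec.from_dict(spec.to_dict())
        assert restored == spec
        r1 = syn.generate(spec)
        r2 = syn.generate(restored)
        assert np.array_equal(r1.recording.axes["x"], r2.recording.axes["x"])

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            syn.generate(syn.SyntheticSpec(scenario="moonwalk"))

    def test_noise_applied_through_spec(self):
        base = syn.SyntheticSpec(
            scenario="element", params={"D_signed": 100.0, "K": 1e-9}
        )
        noisy = syn.SyntheticSpec(
            scenario="element", params={"D_signed": 100.0, "K": 1e-9}, noise_sd=0.5
        )
        r0 = syn.generate(base)
        r1 = syn.generate(noisy)
        assert not np.array_equal(r0.recording.axes["x"], r1.recording.axes["x"])
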