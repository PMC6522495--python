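import numpy as np
import pytest

from vcmnet import assays, simulate
from vcmnet.assays import ActivationMap, ForceModel, Trace


def triangle_transient(rate=1000.0, pre=200, rise=100, fall=400, post=300):
    """Flat zero, linear rise 0->1 over `rise` ms, linear fall 1->0 over `fall` ms."""
    v = np.concatenate(
        [
            np.zeros(pre),
            np.linspace(0, 1, rise + 1)[1:],
            np.linspace(1, 0, fall + 1)[1:],
            np.zeros(post),
        ]
    )
    return Trace(v, rate)


class TestPseudoratio:
    def test_direct_substitution(self):
        t = Trace(np.array([1.0, 1.0, 2.0, 1.0]), 10.0)
        dff = assays.pseudoratio(t, (0.0, 0.2), background=0.0)
        assert dff.values[2] == pytest.approx(1.0)
        assert dff.values[0] == pytest.approx(0.0)

    def test_fbase_must_exceed_background(self):
        t = Trace(np.array([1.0, 1.0, 2.0]), 10.0)
        with pytest.raises(ValueError, match="exceed"):
            assays.pseudoratio(t, (0.0, 0.2), background=1.5)

    @pytest.mark.parametrize("gain", [0.5, 3.0, 17.0])
    def test_affine_gain_invariance(self, gain):
        rng = np.random.default_rng(1)
        f = 100 + 50 * rng.random(200)
        a = assays.pseudoratio(Trace(f, 100.0), (0.0, 0.5), background=20.0)
        b = assays.pseudoratio(Trace(gain * f, 100.0), (0.0, 0.5), background=gain * 20.0)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_planted_amplitude_recovered(self):
        trace, truth = simulate.simulate_calcium_trace(simulate.CalciumSimConfig(seed=3))
        dff = assays.pseudoratio(trace, truth.baseline_window, truth.background)
        feats = assays.calcium_features(dff)
        assert feats.amplitude_mean == pytest.approx(truth.amplitude, rel=0.05)


class TestCalciumFeatures:
    def test_triangle_geometry(self):
        feats = assays.calcium_features(triangle_transient(), smooth_window=1)
        row = feats.per_transient.iloc[0]
        assert row["amplitude"] == pytest.approx(1.0)
        assert row["upstroke_time"] == pytest.approx(0.090, abs=1e-9)
        assert row["decay50_time"] == pytest.approx(0.200, abs=1e-9)

    def test_truncated_decay_flagged_missing(self):
        # a complete transient followed by one whose decay is clipped at the
        # end of the recording before reaching 50% of amplitude
        rate = 1000.0
        full = triangle_transient().values
        clipped = np.concatenate([np.linspace(0, 1, 101)[1:], np.linspace(1, 0.8, 51)[1:]])
        feats = assays.calcium_features(
            Trace(np.concatenate([full, clipped]), rate),
            smooth_window=1,
            min_prominence=0.15,  # end-clipped events have reduced prominence
        )
        assert len(feats.per_transient) == 2
        row = feats.per_transient.iloc[1]
        assert bool(row["decay50_missing"])
        assert np.isnan(row["decay50_time"])
        assert not feats.per_transient.iloc[0]["decay50_missing"]

    def test_no_transient_is_an_error(self):
        with pytest.raises(ValueError, match="transient"):
            assays.calcium_features(Trace(np.zeros(100), 100.0))

    def test_planted_kinetics_recovered(self):
        errs_amp, errs_dec = [], []
        for seed in (9, 10, 11):
            trace, truth = simulate.simulate_calcium_trace(
                simulate.CalciumSimConfig(seed=seed)
            )
            dff = assays.pseudoratio(trace, truth.baseline_window, truth.background)
            feats = assays.calcium_features(dff)
            assert len(feats.per_transient) == 10
            errs_amp.append(abs(feats.amplitude_mean - truth.amplitude) / truth.amplitude)
            errs_dec.append(
                abs(feats.decay50_time_mean - truth.decay50_time) / truth.decay50_time
            )
        assert np.mean(errs_amp) <= 0.05
        assert np.mean(errs_dec) <= 0.05


class TestAPFeatures:
    def test_noiseless_waveform_exact_within_one_sample(self):
        cfg = simulate.APSimConfig(noise_sd=0.0)
        v, truth = simulate.simulate_ap_trace(cfg)
        feats = assays.ap_features(v)
        sample_ms = 1000.0 / cfg.sampling_rate
        assert abs(feats.apd50_mean - truth.apd50) <= sample_ms
        assert abs(feats.apd90_mean - truth.apd90) <= sample_ms
        assert feats.amplitude_mean == pytest.approx(truth.amplitude, abs=0.5)
        assert feats.mdp_mean == pytest.approx(truth.mdp, abs=0.5)

    def test_noisy_waveform_within_five_percent(self):
        v, truth = simulate.simulate_ap_trace(simulate.APSimConfig(seed=1))
        feats = assays.ap_features(v)
        assert feats.apd50_mean == pytest.approx(truth.apd50, rel=0.05)
        assert feats.apd90_mean == pytest.approx(truth.apd90, rel=0.05)

    def test_constant_trace_has_no_ap(self):
        with pytest.raises(ValueError, match="no action potential"):
            assays.ap_features(Trace(np.full(2000, -60.0), 1000.0))

    def test_firing_rate_of_regular_train(self):
        v, _ = simulate.simulate_ap_trace(simulate.APSimConfig(noise_sd=0.0, n_beats=5))
        feats = assays.ap_features(v)
        assert feats.firing_rate == pytest.approx(1.00, abs=1e-9)
        assert len(feats.per_ap) == 5

    def test_single_ap_firing_rate_undefined(self):
        v, _ = simulate.simulate_ap_trace(simulate.APSimConfig(noise_sd=0.0, n_beats=1))
        feats = assays.ap_features(v)
        assert np.isnan(feats.firing_rate)

    def test_invariants_hold_under_noise(self):
        for seed in range(5):
            v, _ = simulate.simulate_ap_trace(simulate.APSimConfig(seed=seed))
            feats = assays.ap_features(v)
            per = feats.per_ap
            assert (per["apd90"] >= per["apd50"]).all()
            assert (per["apd50"] > 0).all()
            assert (per["mdp"] < per["mdp"] + per["amplitude"]).all()


class TestForce:
    def test_cantilever_proportionality(self):
        d = Trace(np.array([0.0, 10.0, 0.0]), 10.0, kind="deflection")
        f = assays.force_from_deflection(d, ForceModel("cantilever", k=0.5))
        assert f.values[1] == pytest.approx(5.0)
        assert f.values[0] == 0.0

    def test_beam_bending_constant(self):
        model = ForceModel("beam", E=2.0, I=3.0, L=2.0)
        assert model.stiffness == pytest.approx(3 * 2.0 * 3.0 / 8.0)

    @pytest.mark.parametrize("mode_kwargs", [
        {"mode": "cantilever", "k": 0.4},
        {"mode": "beam", "E": 1.2, "I": 0.8, "L": 1.5},
    ])
    def test_linearity_in_deflection(self, mode_kwargs):
        rng = np.random.default_rng(2)
        d = rng.random(50)
        model = ForceModel(**mode_kwargs)
        f1 = assays.force_from_deflection(Trace(d, 10.0), model).values
        f2 = assays.force_from_deflection(Trace(2 * d, 10.0), model).values
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-12)

    def test_invalid_models(self):
        with pytest.raises(ValueError):
            ForceModel("cantilever", k=-1.0)
        with pytest.raises(ValueError):
            ForceModel("beam", E=1.0, I=1.0)
        with pytest.raises(ValueError):
            ForceModel("lever")

    def test_planted_twitch_force_round_trip(self):
        cfg = simulate.ForceSimConfig(seed=2)
        d, truth = simulate.simulate_force_trace(cfg)
        f = assays.force_from_deflection(d, ForceModel("cantilever", k=cfg.spring_constant))
        tw = assays.twitch_forces(f)
        assert len(tw) == cfg.n_twitches
        assert tw["twitch_force"].mean() == pytest.approx(truth, rel=0.02)


class TestConductionVelocity:
    def test_planar_wave_exact(self):
        amap, truth = simulate.simulate_activation_map(
            simulate.MapSimConfig(mode="planar", cv_mm_s=50.0, jitter_ms=0.0)
        )
        cv, direction = assays.conduction_velocity(amap)
        assert cv == pytest.approx(50.0, rel=1e-9)
        np.testing.assert_allclose(direction, [1.0, 0.0], atol=1e-9)

    def test_uniform_map_degenerate(self):
        amap = ActivationMap(np.full((10, 10), 5.0), 0.25)
        with pytest.raises(ValueError, match="degenerate"):
            assays.conduction_velocity(amap)

    def test_collinear_pixels_rank_deficient(self):
        times = np.full((5, 5), np.nan)
        times[2, :] = np.arange(5.0)
        with pytest.raises(ValueError, match="collinear|activated"):
            assays.conduction_velocity(ActivationMap(times, 1.0))

    def test_too_few_pixels(self):
        times = np.full((3, 3), np.nan)
        times[0, :3] = [0.0, 1.0, 2.0]
        with pytest.raises(ValueError, match="10 activated"):
            assays.conduction_velocity(ActivationMap(times, 1.0))

    def test_offset_and_rotation_invariance(self):
        amap, _ = simulate.simulate_activation_map(
            simulate.MapSimConfig(mode="planar", cv_mm_s=64.0, jitter_ms=1.0, seed=5)
        )
        cv0, dir0 = assays.conduction_velocity(amap)
        shifted = ActivationMap(amap.times + 123.4, amap.pixel_pitch)
        cv1, dir1 = assays.conduction_velocity(shifted)
        assert cv1 == pytest.approx(cv0, rel=1e-9)
        np.testing.assert_allclose(dir1, dir0, atol=1e-9)
        rotated = ActivationMap(np.rot90(amap.times), amap.pixel_pitch)
        cv2, dir2 = assays.conduction_velocity(rotated)
        assert cv2 == pytest.approx(cv0, rel=1e-9)
        # 90-degree rotation: speed unchanged, gradient rotated
        cross_z = dir2[0] * dir0[1] - dir2[1] * dir0[0]
        assert abs(abs(cross_z) - 1.0) < 1e-6

    def test_radial_wave_far_field_sector(self):
        amap, truth = simulate.simulate_activation_map(simulate.MapSimConfig(seed=4))
        sector = amap.subgrid(slice(16, 25), slice(20, 40))
        cv, _ = assays.conduction_velocity(sector)
        assert cv == pytest.approx(truth, rel=0.10)


class TestFoldChange:
    @pytest.mark.parametrize("shift,fold", [(0.0, 1.0), (-1.0, 2.0), (2.0, 0.25)])
    def test_analytic_values(self, shift, fold):
        assert assays.ddct_fold_change(20 + shift, 15.0, 20.0, 15.0) == pytest.approx(fold)

    def test_planted_fold_change_round_trip(self):
        fold = 3.5
        ct_target_sample = 20.0 - np.log2(fold)
        got = assays.ddct_fold_change(ct_target_sample, 15.0, 20.0, 15.0)
        assert got == pytest.approx(fold, abs=1e-9)

    def test_missing_ct_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            assays.ddct_fold_change(np.nan, 15.0, 20.0, 15.0)
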