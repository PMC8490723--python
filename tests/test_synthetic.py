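"""Generator tests: cohort draws, belt profile, trial construction and the
imposed-target round trip through the analysis pipeline."""

import numpy as np
import pytest

from slipgait import StudyConfig, analyze_trial, make_cohort, simulate_trial
from slipgait.config import BeltProtocol, GeneratorConfig
from slipgait.synthetic import belt_speed_profile, recovery_mos_model, simulate_study


class TestMakeCohort:
    def test_full_cohort_matches_group_anthropometry(self):
        profiles = make_cohort(17, 17, seed=1)
        assert len(profiles) == 34
        ya = [p for p in profiles if p.age_group == "YA"]
        oa = [p for p in profiles if p.age_group == "OA"]
        assert len(ya) == 17 and len(oa) == 17
        # group means within 2 standard errors of the emulated cohort
        assert abs(np.mean([p.height for p in ya]) * 100 - 176.1) < 2 * 8.1 / np.sqrt(17)
        assert abs(np.mean([p.height for p in oa]) * 100 - 161.8) < 2 * 7.2 / np.sqrt(17)

    def test_single_participant_cohort_is_valid(self):
        (p,) = make_cohort(1, 0, seed=99)
        assert p.age_group == "YA"
        assert p.height > 0 and p.mass > 0 and p.baseline_mos_sd > 0
        assert 0 < p.adaptation_rate <= 1

    def test_determinism_same_seed(self):
        a = make_cohort(3, 3, seed=7)
        b = make_cohort(3, 3, seed=7)
        assert a == b

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            make_cohort(0, 0, seed=1)

    def test_mos_variability_within_reported_range(self):
        for p in make_cohort(17, 17, seed=3):
            assert 0.4 <= p.baseline_mos_sd <= 3.1


class TestBeltSpeedProfile:
    def test_triangular_peak_value_and_timing(self):
        proto = BeltProtocol()
        t, v = belt_speed_profile(proto, stance_duration=0.70, rate=1000.0)
        # ramp half-width 0.175 s: peak 1.2 + 5*0.175 at 45 % stance
        assert np.max(v) == pytest.approx(2.075, abs=5e-3)
        assert t[np.argmax(v)] / 0.70 == pytest.approx(0.45, abs=0.01)

    def test_zero_acceleration_limit(self):
        proto = BeltProtocol(acceleration=0.0)
        _, v = belt_speed_profile(proto, 0.70, 300.0)
        assert np.allclose(v, 1.2)

    def test_displacement_surplus_closed_form(self):
        proto = BeltProtocol()
        t, v = belt_speed_profile(proto, 0.70, 5000.0)
        surplus = np.trapezoid(v - proto.nominal_speed, t)
        d = 0.70 * (70.0 - 20.0) / 100.0  # acceleration-episode width, s
        assert surplus == pytest.approx(proto.acceleration * d**2 / 4, rel=1e-3)

    def test_speed_never_below_nominal_and_recovers(self):
        proto = BeltProtocol()
        t, v = belt_speed_profile(proto, 0.70, 300.0)
        assert np.all(v >= proto.nominal_speed - 1e-12)
        after = t >= 0.70 * proto.recovery_pct_stance / 100 + 1.0 / 300
        assert np.allclose(v[after], proto.nominal_speed)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            BeltProtocol(onset_pct_stance=70.0, recovery_pct_stance=20.0)


@pytest.fixture(scope="module")
def noise_free():
    cfg = StudyConfig()
    cfg.generator.noise_scale = 0.0
    profile = make_cohort(1, 0, seed=5, config=cfg.generator)[0]
    trial = simulate_trial(profile, cfg.protocol, 1, seed=11,
                           config=cfg.generator)
    return cfg, profile, trial


class TestSimulateTrial:
    def test_round_trip_recovers_imposed_targets(self, noise_free):
        """With noise off, pipeline MoS/step length equal the imposed values."""
        cfg, profile, trial = noise_free
        steps = analyze_trial(trial, profile.height, profile.perturbed_side,
                              cfg.analysis)
        imposed = {s["label"]: s for s in trial.annotations["steps"] if s["label"]}
        assert len(steps) == 18  # Pre2, Pre1, Pert, Rec1..Rec15
        for sm in steps:
            tgt = imposed[sm.step_label]
            assert sm.mos_cm == pytest.approx(tgt["mos_cm"], abs=0.05)
            assert sm.step_len_pctbh == pytest.approx(tgt["step_len_pctbh"],
                                                      abs=0.05)

    def test_noise_free_mos_follows_recovery_model(self, noise_free):
        cfg, profile, trial = noise_free
        imposed = {s["label"]: s["mos_cm"] for s in trial.annotations["steps"]
                   if s["label"]}
        for k in range(1, 16):
            expected = float(recovery_mos_model(profile, 1, k))
            assert imposed[f"Rec{k}"] == pytest.approx(expected, abs=1e-9)

    def test_unperturbed_trial_has_constant_belt(self):
        cfg = StudyConfig()
        profile = make_cohort(1, 0, seed=5, config=cfg.generator)[0]
        trial = simulate_trial(profile, cfg.protocol, 0, seed=11,
                               config=cfg.generator)
        assert trial.pert_hs_time is None
        for side in ("left", "right"):
            assert np.allclose(trial.belt_speed[side], 1.2)

    def test_slip_trial_has_single_belt_episode(self):
        cfg = StudyConfig()
        profile = make_cohort(1, 0, seed=5, config=cfg.generator)[0]
        trial = simulate_trial(profile, cfg.protocol, 2, seed=11,
                               config=cfg.generator)
        v = trial.belt_speed[profile.perturbed_side]
        accel = v > 1.2 + 1e-9
        starts = np.flatnonzero(np.diff(accel.astype(int)) == 1)
        assert len(starts) == 1
        other = "left" if profile.perturbed_side == "right" else "right"
        assert np.allclose(trial.belt_speed[other], 1.2)

    def test_grf_vert_nonnegative_and_pert_stance_quicker(self):
        cfg = StudyConfig()
        profile = make_cohort(1, 0, seed=5, config=cfg.generator)[0]
        trial = simulate_trial(profile, cfg.protocol, 1, seed=11,
                               config=cfg.generator)
        for side in ("left", "right"):
            assert np.all(trial.grf_vert[side] >= 0)
        steps = {s["label"]: s for s in trial.annotations["steps"] if s["label"]}
        assert steps["Pert"]["stance"] <= steps["Pre2"]["stance"]

    def test_invalid_slip_index_rejected(self):
        cfg = StudyConfig()
        profile = make_cohort(1, 0, seed=5, config=cfg.generator)[0]
        with pytest.raises(ValueError):
            simulate_trial(profile, cfg.protocol, 11, seed=1,
                           config=cfg.generator)

    def test_expected_recovery_amplitude_non_increasing_across_slips(self):
        profile = make_cohort(1, 0, seed=5)[0]
        amp = [
            profile.recovery_amplitude * profile.adaptation_rate ** (s - 1)
            for s in range(1, 11)
        ]
        assert np.all(np.diff(amp) <= 0)


class TestSimulateStudy:
    def test_counts_and_determinism(self, small_config):
        ds = simulate_study(small_config, seed=4)
        assert len(ds.participants) == 4
        assert len(ds.trials) == 4 * 3  # Normal + 2 slips each
        ds2 = simulate_study(small_config, seed=4)
        t1 = ds.trials[(ds.participants[0].id, 1)]
        t2 = ds2.trials[(ds2.participants[0].id, 1)]
        assert np.array_equal(t1.com_ap, t2.com_ap)
        assert np.array_equal(t1.grf_vert["left"], t2.grf_vert["left"])
        assert ds.config_echo == ds2.config_echo

    def test_different_seeds_differ_but_share_config(self, small_config):
        a = simulate_study(small_config, seed=4)
        b = simulate_study(small_config, seed=5)
        ta = a.trials[(a.participants[0].id, 1)]
        tb = b.trials[(b.participants[0].id, 1)]
        assert not np.array_equal(ta.com_ap, tb.com_ap)
        assert a.config_echo == b.config_echo
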