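"""Balance-outcome tests: XCoM, MoS, step length, GRF angle, baseline and
the n_steps recovery criterion (with an independent brute-force oracle)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slipgait.stability import (
    CAPPED_N_STEPS,
    baseline_stats,
    grf_angle,
    margin_of_stability,
    n_steps,
    step_length_pct,
    xcom,
)


def brute_force_n_steps(values, mean, sd, window=3):
    """Independent oracle: scan every window of three consecutive steps."""
    inband = [mean - sd <= v <= mean + sd for v in values]
    for k in range(len(values) - window + 1):
        if all(inband[k : k + window]):
            return k + 1
    return CAPPED_N_STEPS


class TestXcom:
    def test_zero_velocity_identity(self):
        assert xcom(0.30, 0.0, 3.0) == pytest.approx(0.30)

    def test_hand_computed_value(self):
        omega0 = np.sqrt(9.81 / 1.0)
        assert xcom(0.30, 1.2, omega0) == pytest.approx(0.6831, abs=1e-4)

    def test_negative_velocity_moves_xcom_backwards(self):
        assert xcom(0.30, -0.5, 3.0) < 0.30

    def test_rejects_nonpositive_omega0(self):
        with pytest.raises(ValueError):
            xcom(0.3, 0.1, 0.0)


class TestMarginOfStability:
    @pytest.mark.parametrize(
        "toe, xc, expected", [(0.50, 0.45, 5.0), (0.45, 0.45, 0.0),
                              (0.40, 0.45, -5.0)]
    )
    def test_sign_convention(self, toe, xc, expected):
        """XCoM behind the anterior boundary <=> positive MoS."""
        assert margin_of_stability(toe, xc) == pytest.approx(expected)


class TestStepLength:
    def test_percent_body_height(self):
        assert step_length_pct(0.600, 0.072, 1.76) == pytest.approx(30.0)

    def test_equal_feet_give_zero(self):
        assert step_length_pct(0.4, 0.4, 1.7) == 0.0

    def test_doubling_height_halves_result(self):
        a = step_length_pct(0.7, 0.1, 1.6)
        b = step_length_pct(0.7, 0.1, 3.2)
        assert a == pytest.approx(2 * b)

    def test_rejects_nonpositive_height(self):
        with pytest.raises(ValueError):
            step_length_pct(0.5, 0.1, 0.0)


class TestGrfAngle:
    @pytest.mark.parametrize(
        "ap, vert, expected", [(0.0, 700.0, 0.0), (700.0, 700.0, 45.0),
                               (-100.0, 700.0, -8.13)]
    )
    def test_reference_angles(self, ap, vert, expected):
        assert grf_angle(ap, vert) == pytest.approx(expected, abs=0.01)

    def test_odd_in_first_argument_and_bounded(self):
        ap = np.linspace(-2000, 2000, 41)
        th = grf_angle(ap, 700.0)
        assert np.allclose(th, -grf_angle(-ap, 700.0))
        assert np.all(np.abs(th) < 90.0)

    def test_nonpositive_vertical_force_masked(self):
        out = grf_angle(np.array([10.0, 10.0]), np.array([700.0, 0.0]))
        assert np.isfinite(out[0]) and np.isnan(out[1])


class TestBaselineStats:
    def test_constant_cycles(self):
        b = baseline_stats([4.6] * 5)
        assert b.mos_mean == 4.6 and b.mos_sd == 0.0 and b.n_cycles == 5

    def test_sample_standard_deviation(self):
        b = baseline_stats([3, 4, 5, 6, 7])
        assert b.mos_mean == pytest.approx(5.0)
        assert b.mos_sd == pytest.approx(1.5811, abs=1e-4)

    def test_single_cycle_rejected(self):
        with pytest.raises(ValueError):
            baseline_stats([4.6])


class TestNSteps:
    def test_reference_sequence_recovers_at_step_three(self):
        """Baseline 4.6 +- 1.3: steps 3-5 are the first in-band triple."""
        base = baseline_stats([4.6, 4.6, 4.6, 4.6, 4.6])
        base.mos_sd = 1.3
        seq = [-1.0, 0.5, 3.4, 4.0, 5.1, 2.0, 4.6, 4.4, 5.0, 4.6, 4.6, 4.6,
               4.6, 4.6, 4.6]
        out = n_steps(seq, base)
        assert out.n_steps == 3 and not out.capped
        assert out.n_steps == brute_force_n_steps(seq, 4.6, 1.3)

    def test_immediately_stable_gait(self):
        base = baseline_stats([4.0, 5.0, 4.5, 4.5, 5.0])
        out = n_steps([base.mos_mean] * 15, base)
        assert out.n_steps == 1 and not out.capped

    def test_never_recovering_is_capped_at_16(self):
        base = baseline_stats([4.0, 5.0, 4.5, 4.5, 5.0])
        out = n_steps([base.mos_mean - 5 * base.mos_sd] * 15, base)
        assert out.n_steps == CAPPED_N_STEPS and out.capped

    def test_wrong_length_rejected(self):
        base = baseline_stats([4, 5, 6])
        with pytest.raises(ValueError):
            n_steps([4.0] * 14, base)

    def test_nonfinite_values_rejected(self):
        base = baseline_stats([4, 5, 6])
        with pytest.raises(ValueError):
            n_steps([np.nan] + [4.0] * 14, base)

    @given(
        st.lists(st.floats(-5, 15), min_size=15, max_size=15),
        st.floats(3.0, 6.0),
        st.floats(0.4, 3.1),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, seq, mean, sd):
        base = baseline_stats([mean, mean])
        base.mos_sd = sd
        out = n_steps(seq, base)
        assert out.n_steps == brute_force_n_steps(seq, mean, sd)
        assert out.capped == (out.n_steps == CAPPED_N_STEPS)

    def test_monotone_under_contraction_towards_baseline(self):
        """Pulling every recovery value towards the baseline mean can only
        shorten (never lengthen) the recovery."""
        rng = np.random.default_rng(42)
        base = baseline_stats([4.6, 4.6])
        base.mos_sd = 1.3
        for _ in range(200):
            seq = rng.normal(3.0, 3.0, size=15)
            n0 = n_steps(seq, base).n_steps
            for lam in (0.25, 0.5, 0.75, 1.0):
                contracted = base.mos_mean + (1 - lam) * (seq - base.mos_mean)
                assert n_steps(contracted, base).n_steps <= n0
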