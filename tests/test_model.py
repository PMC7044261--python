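"""Unit and property tests for the combination models and their readouts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from binsum.model import (
    NonBracketableError,
    dipper_curve,
    eeg_response_curve,
    gain_control_response,
    increment_threshold,
    increment_thresholds,
    linear_sum_response,
    snr_transform,
    tagged_response,
    to_db,
)
from binsum.params import TABLE1, ModelParams
from binsum.stimuli import F35, F40, EarSignal, eeg_arrangement, psych_intervals

TEST_PARAMS = ModelParams(p=2.0, q=2.0, Z=10.0, sigma40=0.01, omega=1.0)


class TestGainControlResponse:
    def test_zero_input_gives_zero(self):
        assert gain_control_response(0.0, 0.0, TABLE1["6a"]) == 0.0
        assert gain_control_response(0.0, 0.0, TEST_PARAMS) == 0.0

    def test_hand_computed_value(self):
        # p=q=2, Z=10, w=1, C=10 each: 2*100/(100+100+100) = 2/3
        assert gain_control_response(10.0, 10.0, TEST_PARAMS) == pytest.approx(
            2.0 / 3.0, abs=1e-12
        )

    def test_pinned_published_params_evaluation(self):
        # independent high-precision scalar evaluation, frozen
        assert gain_control_response(50.0, 50.0, TABLE1["6a"]) == pytest.approx(
            8.844519508324577, rel=1e-12
        )

    @settings(derandomize=True, max_examples=60)
    @given(
        cl=st.floats(0, 100),
        cr=st.floats(0, 100),
        key=st.sampled_from(["6a", "6b", "6d"]),
    )
    def test_symmetric_finite_nonnegative(self, cl, cr, key):
        params = TABLE1[key]
        a = gain_control_response(cl, cr, params)
        b = gain_control_response(cr, cl, params)
        assert a == b
        assert np.isfinite(a) and a >= 0

    @pytest.mark.parametrize("key", ["6a", "6d"])
    def test_nondecreasing_over_input_grid_weak_suppression(self, key):
        # with weak suppression the response never decreases as either
        # input grows
        params = TABLE1[key]
        c = np.linspace(0, 100, 60)
        resp = gain_control_response(c[:, None], c[None, :], params)
        assert np.all(np.diff(resp, axis=0) >= -1e-12)
        assert np.all(np.diff(resp, axis=1) >= -1e-12)

    def test_strictly_increasing_without_suppression(self):
        params = TABLE1["6a"].replace(omega=0.0)
        c = np.linspace(0.0, 100.0, 60)
        resp = gain_control_response(c[:, None], c[None, :], params)
        assert np.all(np.diff(resp, axis=0) > 0)
        assert np.all(np.diff(resp, axis=1) > 0)

    @pytest.mark.parametrize("key", ["6b", "6e"])
    def test_near_monotone_under_full_suppression(self, key):
        # at omega = 1 cross-channel suppression can marginally exceed the
        # own-channel gain: decrements exist but are a <1% ripple
        params = TABLE1[key]
        c = np.linspace(0, 100, 60)
        resp = gain_control_response(c[:, None], c[None, :], params)
        floor = -1e-2 * resp.max()
        assert np.all(np.diff(resp, axis=0) >= floor)
        assert np.all(np.diff(resp, axis=1) >= floor)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gain_control_response(-1.0, 0.0, TEST_PARAMS)
        with pytest.raises(ValueError):
            gain_control_response(np.nan, 0.0, TEST_PARAMS)
        with pytest.raises(ValueError):
            gain_control_response(1.0, 1.0, TABLE1["7a"])  # no omega


class TestLinearSumResponse:
    def test_zero_and_closed_form(self):
        assert linear_sum_response(0.0, 0.0, TEST_PARAMS) == 0.0
        # p=q=2, Z=10, total 10: 100/(100+100) = 1/2
        assert linear_sum_response(5.0, 5.0, TEST_PARAMS) == pytest.approx(
            0.5, abs=1e-12
        )

    @settings(derandomize=True, max_examples=40)
    @given(total=st.floats(0.1, 150), frac=st.floats(0, 1))
    def test_depends_only_on_total_depth(self, total, frac):
        params = TABLE1["7a"]
        split = linear_sum_response(total * frac, total * (1 - frac), params)
        mon = linear_sum_response(total, 0.0, params)
        assert split == pytest.approx(mon, rel=1e-12)


class TestTaggedResponse:
    def test_same_tag_reduces_to_gain_control(self, p6d):
        left, right = eeg_arrangement("bin", 25.0)
        assert tagged_response(left, right, F40, p6d) == pytest.approx(
            gain_control_response(25.0, 25.0, p6d), rel=1e-12
        )

    def test_cross_binaural_single_excitatory_term(self, p6d):
        # left m@40, right m@35: 40 Hz readout has one excitatory term but
        # full cross-ear suppression
        m = 25.0
        left, right = eeg_arrangement("cross_bin", m)
        expect = m**p6d.p / (p6d.Z**p6d.q + m**p6d.q + p6d.omega * m**p6d.q)
        assert tagged_response(left, right, F40, p6d) == pytest.approx(
            expect, rel=1e-12
        )

    def test_pinned_cross_dichotic_masker_readout(self, p6d):
        # masker 50% @35 in one ear, signal 100% @40 in the other
        left, right = eeg_arrangement("cross_dich", 100.0)
        assert tagged_response(left, right, F35, p6d) == pytest.approx(
            3.0926148753636897, rel=1e-12
        )

    def test_unknown_tag_rejected(self, p6d):
        with pytest.raises(ValueError):
            tagged_response(EarSignal(10.0, F40), EarSignal(0.0, None), 45.0, p6d)


class TestSnrTransform:
    def test_baseline_and_affine_points(self):
        assert snr_transform(0.0, 2.0) == 1.0
        assert snr_transform(2.0, 2.0) == 2.0

    def test_pinned_masker_only_snr(self, p6d):
        left, right = eeg_arrangement("dich", 0.0)
        resp = tagged_response(left, right, F40, p6d)
        assert snr_transform(resp, p6d.sigma40) == pytest.approx(
            3.5650577112639112, rel=1e-12
        )

    def test_strictly_increasing_and_guards(self):
        r = np.linspace(0, 10, 11)
        assert np.all(np.diff(snr_transform(r, 0.5)) > 0)
        with pytest.raises(ValueError):
            snr_transform(1.0, 0.0)
        with pytest.raises(ValueError):
            snr_transform(1.0, -1.0)


class TestIncrementThreshold:
    def test_detection_closed_form(self):
        # omega=0, mon, pedestal 0: T^2/(100+T^2) = 0.01 -> T = 1.00504...
        params = ModelParams(p=2.0, q=2.0, Z=10.0, sigma40=0.01, omega=0.0)
        assert increment_threshold("mon", 0.0, params) == pytest.approx(
            1.0050378152592121, rel=1e-6
        )

    def test_pedestal_zero_arrangements_identical(self, p6a):
        t = [increment_threshold(c, 0.0, p6a) for c in ("mon", "dich", "half_bin")]
        assert t[0] == pytest.approx(t[1], rel=1e-9)
        assert t[0] == pytest.approx(t[2], rel=1e-9)

    def test_dip_bottom_near_published_value(self, p6a):
        # binaural threshold dips to ~2% on an 8% pedestal
        assert increment_threshold("bin", 8.0, p6a) == pytest.approx(2.0, abs=0.5)

    def test_dipper_shape_facilitation_then_masking(self, p6a):
        db = dipper_curve("bin", [0, 1, 2, 4, 8, 16, 32, 64], p6a)
        i_min = int(np.argmin(db))
        assert 0 < i_min < 7          # interior dip
        assert db[i_min] < db[0] - 3  # facilitation region
        assert db[-1] > db[0]         # masking handle overtakes detection

    def test_criterion_unreachable_raises(self, p6a):
        with pytest.raises(NonBracketableError):
            increment_threshold("mon", 0.0, p6a, criterion=1e9)
        with pytest.raises(NonBracketableError):
            # criterion already met at the lower bracket
            increment_threshold(
                "mon", 0.0, ModelParams(p=2.0, q=2.0, Z=1e-3, sigma40=1.0, omega=0.0),
                criterion=1e-12,
            )

    def test_weak_suppression_handles_stay_separated(self, p6a):
        peds = [32.0, 64.0]
        mon = dipper_curve("mon", peds, p6a)
        bin_ = dipper_curve("bin", peds, p6a)
        sep = mon - bin_
        assert np.all(sep > 3.0)              # clearly apart
        assert abs(sep[0] - sep[1]) < 1.0     # near-parallel

    def test_strong_suppression_handles_converge(self):
        p6b = TABLE1["6b"]
        peds = [32.0, 64.0]
        sep = dipper_curve("mon", peds, p6b) - dipper_curve("bin", peds, p6b)
        assert np.all(np.abs(sep) < 1.5)


class TestEEGResponseCurve:
    def test_no_signal_no_masker_baseline(self, p6d):
        snr = eeg_response_curve("mon", [0.0], p6d)
        assert snr[F40][0] == pytest.approx(1.0)
        assert snr[F35][0] == pytest.approx(1.0)

    def test_binaural_exceeds_monaural_everywhere(self, p6d):
        depths = [6.25, 12.5, 25, 50, 100]
        mon = eeg_response_curve("mon", depths, p6d, freqs=[F40])[F40]
        bin_ = eeg_response_curve("bin", depths, p6d, freqs=[F40])[F40]
        assert np.all(bin_ > mon)

    def test_cross_dichotic_masker_declines_gently(self, p6d):
        depths = [6.25, 12.5, 25, 50, 100]
        cd35 = eeg_response_curve("cross_dich", depths, p6d, freqs=[F35])[F35]
        assert np.all(np.diff(cd35) < 0)       # monotone decline
        assert cd35[0] - cd35[-1] < 1.5        # but gentle

    def test_missing_sigma35_raises(self, p6a):
        with pytest.raises(ValueError):
            eeg_response_curve("cross_bin", [25.0], p6a, freqs=[F35])


def test_interval_arrangements_match_design():
    # monaural: pedestal+target one ear, carrier in the other
    assert psych_intervals("mon", 8.0, 2.0) == ((8.0, 0.0), (10.0, 0.0))
    assert psych_intervals("bin", 8.0, 2.0) == ((8.0, 8.0), (10.0, 10.0))
    assert psych_intervals("dich", 8.0, 2.0) == ((8.0, 0.0), (8.0, 2.0))
    assert psych_intervals("half_bin", 8.0, 2.0) == ((8.0, 8.0), (10.0, 8.0))
    # detection: mon/dich/half_bin resolve to the same stimulus up to ear
    # relabelling (target in one ear, plain carrier in the other)
    as_sets = [
        tuple(sorted(ival) for ival in psych_intervals(c, 0.0, 2.0))
        for c in ("mon", "dich", "half_bin")
    ]
    assert as_sets[0] == as_sets[1] == as_sets[2]


def test_vectorized_solver_matches_scalar_calls(p6a):
    cells = [("mon", 8.0), ("bin", 8.0), ("dich", 16.0), ("half_bin", 4.0)]
    vec = increment_thresholds([c for c, _ in cells], [P for _, P in cells], p6a)
    for (cond, P), v in zip(cells, vec):
        assert increment_threshold(cond, P, p6a) == pytest.approx(v, rel=1e-9)
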