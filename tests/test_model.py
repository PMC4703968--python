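"""Recursion, steady states, protocols, and weight-sequence serialization."""

import io
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stpsim import (
    Branch,
    ParameterDomainError,
    ProtocolError,
    PulseProtocol,
    STPParams,
    WeightSequence,
    depression_weights,
    eval_params,
    facilitation_weights,
    saturation_index,
    steady_state,
    weights_for_intervals,
)

from conftest import TABLE_ROWS


def iterate_oracle(f: float, k: float, intensity: float, branch: str, n: int) -> list:
    """Independent plain-Python recursion, kept free of library internals."""
    out = [1.0]
    state = 1.0
    for _ in range(n - 1):
        if branch == "depression":
            released = state * (1 - f)
            state = released + k * (1 - released)
            out.append(intensity * state)
        else:
            decayed = (1 - f) * state
            state = decayed + k * (intensity - decayed)
            out.append(state)
    return out


class TestDepressionWeights:
    def test_low_frequency_weights_stay_at_unity(self):
        # 1 Hz parameters: peaks do not vary with input number
        w = depression_weights(STPParams("depression", 0.0038, 0.676), 40)
        assert np.all(w.weights >= 0.99) and np.all(w.weights <= 1.0)

    def test_full_recovery_gives_constant_weights(self):
        w = depression_weights(STPParams("depression", 0.37, 1.0), 25)
        np.testing.assert_allclose(w.weights, 1.0, rtol=0, atol=1e-15)

    def test_high_frequency_converges_to_derived_steady_state(self):
        # frozen from the closed form k/(1-(1-f)(1-k)) at the 142 Hz row
        w = depression_weights(STPParams("depression", 0.145, 0.219), 2000)
        assert w.weights[-1] == pytest.approx(0.6591521317100333, rel=1e-12)

    def test_matches_independent_oracle(self):
        w = depression_weights(STPParams("depression", 0.083, 0.304), 30)
        np.testing.assert_allclose(
            w.weights, iterate_oracle(0.083, 0.304, 1.0, "depression", 30),
            rtol=0, atol=1e-14,
        )

    @pytest.mark.parametrize("n", [0, -3])
    def test_rejects_empty_trains(self, n):
        with pytest.raises(ProtocolError):
            depression_weights(STPParams("depression", 0.1, 0.5), n)

    def test_rejects_wrong_branch(self):
        with pytest.raises(ParameterDomainError):
            depression_weights(STPParams("facilitation", 0.1, 0.5, 1.5), 10)


class TestFacilitationWeights:
    def test_low_frequency_weights_stay_at_unity(self):
        w = facilitation_weights(STPParams("facilitation", 0.643, 0.521, 1.582), 40)
        assert np.all(np.abs(w.weights - 1.0) <= 0.02)

    def test_single_pulse_saturates_ceiling_without_decay(self):
        w = facilitation_weights(STPParams("facilitation", 0.0, 1.0, 2.7), 3)
        assert w.weights[1] == pytest.approx(2.7, abs=1e-15)

    def test_high_frequency_converges_to_derived_steady_state(self):
        w = facilitation_weights(STPParams("facilitation", 0.034, 0.215, 1.582), 4000)
        assert w.weights[-1] == pytest.approx(1.4072986056518684, rel=1e-12)

    def test_matches_independent_oracle(self):
        w = facilitation_weights(STPParams("facilitation", 0.156, 0.267, 1.582), 30)
        np.testing.assert_allclose(
            w.weights, iterate_oracle(0.156, 0.267, 1.582, "facilitation", 30),
            rtol=0, atol=1e-14,
        )

    def test_rejects_sub_unity_ceiling(self):
        with pytest.raises(ParameterDomainError):
            STPParams("facilitation", 0.1, 0.5, 0.9)


class TestSteadyState:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (STPParams("depression", 0.0038, 0.676), 0.998),
            (STPParams("facilitation", 0.0, 1.0, 2.0), 2.0),
            (STPParams("depression", 1.0, 0.5), 0.5),
        ],
    )
    def test_known_fixed_points(self, params, expected):
        assert steady_state(params) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("nu,f_d,k_d,f_f,k_f", TABLE_ROWS)
    def test_agrees_with_long_iteration_both_branches(self, nu, f_d, k_d, f_f, k_f):
        # closed form against a 1e5-step independent iteration
        for branch, f, k, intensity in (
            ("depression", f_d, k_d, 1.0),
            ("facilitation", f_f, k_f, 1.582),
        ):
            state = 1.0
            for _ in range(100_000):
                if branch == "depression":
                    released = state * (1 - f)
                    state = released + k * (1 - released)
                else:
                    decayed = (1 - f) * state
                    state = decayed + k * (intensity - decayed)
            ss = steady_state(STPParams(branch, f, k, intensity))
            final = intensity * state if branch == "depression" else state
            assert abs(ss - final) / ss < 1e-10


@settings(deadline=None, max_examples=60)
@given(
    f=st.floats(0.001, 1.0),
    k=st.floats(0.001, 1.0),
    branch=st.sampled_from(["depression", "facilitation"]),
)
def test_monotone_geometric_convergence(f, k, branch):
    """|W_i - W_inf| contracts by exactly (1-f)(1-k) each step."""
    intensity = 1.0 if branch == "depression" else 1.582
    params = STPParams(branch, f, k, intensity)
    w = (depression_weights if branch == "depression" else facilitation_weights)(
        params, 30
    ).weights
    w_inf = steady_state(params)
    gaps = np.abs(w - w_inf)
    rho = (1 - f) * (1 - k)
    for i in range(len(gaps) - 1):
        assert gaps[i + 1] <= gaps[i] + 1e-12
        if gaps[i] > 1e-8:  # ratio is meaningless once the gap hits round-off
            assert gaps[i + 1] / gaps[i] == pytest.approx(rho, abs=1e-6)


@pytest.mark.parametrize("nu,f_d,k_d,f_f,k_f", TABLE_ROWS)
def test_branch_direction_contracts(nu, f_d, k_d, f_f, k_f):
    """Depression never exceeds its baseline; facilitation never dips below."""
    d = depression_weights(STPParams("depression", f_d, k_d), 40).weights
    f = facilitation_weights(STPParams("facilitation", f_f, k_f, 1.582), 40).weights
    assert np.all(d <= 1.0 + 1e-12)
    assert np.all(f >= 1.0 - 1e-12) or steady_state(
        STPParams("facilitation", f_f, k_f, 1.582)
    ) < 1


def test_steady_state_frequency_monotonicity():
    """Band-pass filtering: depression falls and facilitation rises with rate."""
    dep = [steady_state(STPParams("depression", r[1], r[2])) for r in TABLE_ROWS]
    fac = [steady_state(STPParams("facilitation", r[3], r[4], 1.582)) for r in TABLE_ROWS]
    assert np.all(np.diff(dep) <= 1e-12)
    assert np.all(np.diff(fac) >= -1e-12)


class TestPulseProtocol:
    def test_one_hertz_off_interval_is_995_ms(self):
        p = PulseProtocol.uniform(1.0, 5, width=5.0)
        assert p.intervals == (995.0,) * 4
        assert p.frequency_hz == pytest.approx(1.0)

    def test_instantaneous_frequencies(self):
        p = PulseProtocol(width=5.0, intervals=(995.0, 2.042253521126761))
        np.testing.assert_allclose(p.instantaneous_frequencies(), [1.0, 142.0])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"width": 0.0},
            {"width": -1.0},
            {"intervals": (-5.0,)},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ProtocolError):
            PulseProtocol(**kwargs)

    def test_frequency_too_high_for_width(self):
        with pytest.raises(ProtocolError):
            PulseProtocol.uniform(250.0, 10, width=5.0)


class TestWeightsForIntervals:
    def test_uniform_train_reduces_to_constant_recursion(self, law):
        proto = PulseProtocol.uniform(50.0, 40)
        mixed = weights_for_intervals(
            STPParams("depression", 0.5, 0.5), proto, law
        )
        const = depression_weights(eval_params(law, 50.0, "depression"), 40, proto)
        np.testing.assert_allclose(mixed.weights, const.weights, rtol=0, atol=1e-14)

    def test_long_interval_restores_depressed_state(self, law):
        # alternating 142 Hz / 1 Hz intervals: each long rest pulls the
        # weight back toward 1
        hi = 1000.0 / 142.0 - 5.0
        lo = 995.0
        proto = PulseProtocol(width=5.0, intervals=(hi, hi, hi, lo, hi, hi, lo))
        w = weights_for_intervals(STPParams("depression", 0.5, 0.5), proto, law).weights
        assert w[4] > w[3]  # after the first long rest
        assert w[7] > w[6]
        # one long rest recovers a k_D(1 Hz) ~ 0.68 fraction of the deficit
        assert 1.0 - w[4] < (1.0 - w[3]) * 0.45

    def test_single_pulse_is_unity(self, law):
        proto = PulseProtocol(width=5.0, intervals=())
        w = weights_for_intervals(STPParams("depression", 0.5, 0.5), proto, law)
        assert w.weights.tolist() == [1.0]

    def test_out_of_band_frequency_logs_warning(self, law, caplog):
        proto = PulseProtocol(width=5.0, intervals=(2000.0,))  # ~0.5 Hz
        with caplog.at_level("WARNING", logger="stpsim"):
            weights_for_intervals(STPParams("depression", 0.5, 0.5), proto, law)
        assert any("extrapolating" in r.message for r in caplog.records)


class TestWeightSequenceContract:
    def test_requires_unit_baseline(self):
        proto = PulseProtocol(intervals=(10.0,))
        with pytest.raises(ProtocolError):
            WeightSequence("depression", np.array([0.9, 0.8]), proto)

    def test_length_must_match_protocol(self):
        proto = PulseProtocol(intervals=(10.0,))
        with pytest.raises(ProtocolError):
            WeightSequence("depression", np.array([1.0, 0.9, 0.8]), proto)

    def test_csv_round_trip(self):
        seq = depression_weights(
            STPParams("depression", 0.145, 0.219), 8, PulseProtocol.uniform(142.0, 8)
        )
        text = seq.to_csv()
        back = WeightSequence.from_csv(io.StringIO(text))
        np.testing.assert_allclose(back.weights, seq.weights, rtol=1e-12)
        assert back.branch is Branch.DEPRESSION
        assert back.protocol.frequency_hz == pytest.approx(142.0, rel=1e-9)

    def test_json_round_trip_preserves_all_fields(self):
        seq = facilitation_weights(
            STPParams("facilitation", 0.034, 0.215, 1.582),
            6,
            PulseProtocol.uniform(142.0, 6),
        )
        back = WeightSequence.from_json(seq.to_json())
        np.testing.assert_allclose(back.weights, seq.weights, rtol=0, atol=0)
        assert back.protocol == seq.protocol
        assert back.provenance == seq.provenance
        # and the payload is plain JSON
        payload = json.loads(seq.to_json())
        assert set(payload) == {"branch", "provenance", "weights", "protocol"}


def test_saturation_index_reports_settled_sequences():
    fast = depression_weights(STPParams("depression", 0.5, 0.9), 50).weights
    assert saturation_index(fast) is not None
    slow = depression_weights(STPParams("depression", 0.145, 0.219), 4).weights
    assert saturation_index(slow) is None


@pytest.mark.parametrize(
    "branch,f,k,I",
    [
        ("depression", 0.0, 0.5, 1.0),   # depression needs f > 0
        ("depression", 1.1, 0.5, 1.0),
        ("depression", 0.5, 0.0, 1.0),
        ("depression", 0.5, 0.5, 1.2),   # depression baseline is exactly 1
        ("facilitation", 0.5, 1.2, 1.5),
    ],
)
def test_parameter_domain_enforced(branch, f, k, I):
    with pytest.raises(ParameterDomainError):
        STPParams(branch, f, k, I)
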