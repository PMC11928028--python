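"""Unit and property tests for the two-channel membrane-potential model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilm_electro.hh_membrane import (GateSigmoid, HHParams, MembraneState,
                                         StimulusProgram, gate_steady_state,
                                         irradiance_from_power, make_variant,
                                         simulate_membrane, tht_readout)
from biofilm_electro.trace_analysis import count_hyperpolarization_events


class TestGateSteadyState:
    @pytest.mark.parametrize(
        "V, v_half, slope, expected",
        [
            (-60.0, -60.0, 5.0, 0.5),  # midpoint
            (1e4, -60.0, 5.0, 1.0),  # saturation with positive slope
            (-55.0, -60.0, 5.0, 1.0 / (1.0 + math.exp(-1.0))),  # one slope above
        ],
    )
    def test_logistic_values(self, V, v_half, slope, expected):
        gate = GateSigmoid(v_half=v_half, slope=slope)
        assert gate_steady_state(V, gate) == pytest.approx(expected, abs=1e-9)

    def test_rejects_non_finite_voltage(self):
        gate = GateSigmoid(v_half=-60.0, slope=5.0)
        with pytest.raises(ValueError, match="finite"):
            gate_steady_state(float("nan"), gate)

    def test_rejects_zero_slope(self):
        with pytest.raises(ValueError, match="slope"):
            GateSigmoid(v_half=-60.0, slope=0.0)

    @given(
        v1=st.floats(-200, 50),
        v2=st.floats(-200, 50),
        v_half=st.floats(-150, -20),
        slope=st.floats(0.5, 20),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_voltage(self, v1, v2, v_half, slope):
        gate = GateSigmoid(v_half=v_half, slope=slope)
        lo, hi = sorted((v1, v2))
        assert gate_steady_state(lo, gate) <= gate_steady_state(hi, gate) + 1e-12


class TestIrradiance:
    def test_zero_power(self):
        assert irradiance_from_power(0.0, 26.5, 60.0) == 0.0

    def test_working_value(self):
        # 2.43 uW through the FN 26.5 mm, 60x objective: the field of view
        # has diameter 26.5/60 mm, giving ~15.9 uW/mm^2 (the published
        # working irradiance is quoted as 15.99)
        I = irradiance_from_power(2.43, 26.5, 60.0)
        area = math.pi * (26.5 / 120.0) ** 2
        assert I == pytest.approx(2.43 / area, rel=1e-12)
        assert I == pytest.approx(15.9, abs=0.2)

    def test_linear_in_power(self):
        one = irradiance_from_power(1.7, 26.5, 60.0)
        two = irradiance_from_power(3.4, 26.5, 60.0)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_zero_magnification_rejected(self):
        with pytest.raises(ValueError):
            irradiance_from_power(1.0, 26.5, 0.0)


class TestThTReadout:
    def test_constant_voltage_constant_intensity(self):
        trace = tht_readout(np.full(10, -80.0))
        assert np.allclose(trace.intensity, trace.intensity[0])

    def test_monotone_decreasing_in_voltage(self):
        trace = tht_readout(np.array([-140.0, -120.0, -100.0, -80.0]),
                            normalize=False)
        assert np.all(np.diff(trace.intensity) < 0)

    def test_nernstian_ratio(self):
        # a 26 mV hyperpolarization step brightens by a factor e
        trace = tht_readout(np.array([-60.0, -86.0]), v_thermal=26.0,
                            normalize=False)
        assert trace.intensity[1] / trace.intensity[0] == pytest.approx(
            math.e, rel=1e-12
        )

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tht_readout(np.array([]))


class TestVariants:
    def test_wildtype_identity(self, hh_params):
        assert make_variant(hh_params, "wildtype") is hh_params

    def test_delta_kch_zeroes_kch(self, hh_params):
        variant = make_variant(hh_params, "delta_kch")
        assert variant.g_K == 0.0
        assert variant.g_Q == hh_params.g_Q

    def test_catalase_zeroes_ros(self, hh_params):
        assert make_variant(hh_params, "catalase").alpha_ROS == 0.0

    def test_ms_knockout_zeroes_q(self, hh_params):
        assert make_variant(hh_params, "ms_knockout").g_Q == 0.0

    def test_unknown_variant_lists_valid_names(self, hh_params):
        with pytest.raises(ValueError, match="wildtype"):
            make_variant(hh_params, "nonsense")


class TestParamInvariants:
    def test_default_timescale_ordering(self, hh_params):
        assert hh_params.tau_act_Q < hh_params.tau_act_K
        assert hh_params.tau_inact_Q > hh_params.tau_deact_K

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(C_m=-1.0),
            dict(g_L=0.0),
            dict(tau_act_Q=2.0),  # violates tau_act_Q < tau_act_K
            dict(tau_deact_K=5.0),  # violates tau_inact_Q > tau_deact_K
            dict(E_K=-50.0),  # above rest
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HHParams(**kwargs)


class TestSimulation:
    def test_phenotype_peak_counts(self, variant_traces):
        """The four variants reproduce the observed event counts: two
        hyperpolarizations for the wildtype, a single peak-plus-plateau for
        the Kch deletion, a single transient for ROS scavenging, and no
        spike dynamics for the mechanosensitive knockouts."""
        expected = {"wildtype": 2, "delta_kch": 1, "catalase": 1,
                    "ms_knockout": 0}
        counts = {
            variant: count_hyperpolarization_events(trace)
            for variant, (_, trace) in variant_traces.items()
        }
        assert counts == expected

    def test_delta_kch_has_no_repolarization(self, variant_traces):
        traj, _ = variant_traces["delta_kch"]
        # after the first event the membrane stays deeply hyperpolarized
        late = traj.t > 10.0
        assert np.all(traj.V[late] < -100.0)

    def test_catalase_repolarizes(self, variant_traces):
        traj, _ = variant_traces["catalase"]
        late = traj.t > 30.0
        assert np.all(traj.V[late] > -90.0)

    def test_gates_stay_in_unit_interval(self, variant_traces):
        for _, (traj, _) in variant_traces.items():
            for gate in (traj.m_Q, traj.h_Q, traj.n_K):
                assert np.all(gate >= 0.0) and np.all(gate <= 1.0)
            assert np.all(traj.S >= 0.0)

    def test_gates_bounded_under_random_parameters(self, working_stimulus):
        rng = np.random.default_rng(7)
        for _ in range(5):
            scale = lambda x: float(x * rng.uniform(0.7, 1.3))
            params = HHParams(
                g_Q=scale(1.0), g_K=scale(1.6), g_L=scale(0.3),
                alpha_ROS=scale(0.1),
            )
            traj, _ = simulate_membrane(
                params, StimulusProgram.constant(rng.uniform(5, 40), 30.0)
            )
            for gate in (traj.m_Q, traj.h_Q, traj.n_K):
                assert np.all(gate >= 0.0) and np.all(gate <= 1.0)

    def test_no_light_flat_trace(self, hh_params):
        traj, _ = simulate_membrane(hh_params, StimulusProgram.constant(0.0, 20.0))
        # rest sits within ~1 mV of E_L (tiny resting Kch conductance)
        assert np.all(np.abs(traj.V - hh_params.E_L) < 1.5)
        assert count_hyperpolarization_events(
            simulate_membrane(hh_params, StimulusProgram.constant(0.0, 20.0))[1]
        ) == 0

    def test_zero_conductances_keep_voltage_constant(self, working_stimulus):
        params = HHParams(g_Q=0.0, g_K=0.0, g_L=1e-12)
        traj, _ = simulate_membrane(params, working_stimulus)
        assert np.allclose(traj.V, traj.V[0], atol=1e-6)

    def test_deterministic(self, hh_params, working_stimulus):
        _, a = simulate_membrane(hh_params, working_stimulus)
        _, b = simulate_membrane(hh_params, working_stimulus)
        assert np.array_equal(a.intensity, b.intensity)

    def test_dt_convergence(self, hh_params):
        stim = StimulusProgram.constant(15.99, 30.0)
        _, coarse = simulate_membrane(hh_params, stim, dt=0.01)
        _, fine = simulate_membrane(hh_params, stim, dt=0.005)
        n = min(len(coarse), len(fine))
        rel = np.max(np.abs(coarse.intensity[:n] - fine.intensity[:n]))
        rel /= np.max(np.abs(fine.intensity))
        assert rel < 1e-3

    def test_unstable_dt_rejected(self, hh_params, working_stimulus):
        with pytest.raises(ValueError, match="dt"):
            simulate_membrane(hh_params, working_stimulus, dt=5.0)

    def test_degenerate_stimulus_warns_and_returns_initial(self, hh_params):
        empty = StimulusProgram(schedule=(), total_duration=0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            traj, _ = simulate_membrane(hh_params, empty)
        assert len(traj) == 1

    def test_time_to_first_peak_non_increasing_in_irradiance(self, hh_params):
        """Stronger blue light registers faster (shorter first-peak
        latency), up to the recording cadence."""
        peak_times = []
        for irr in (4.0, 8.0, 12.0, 16.0):
            traj, _ = simulate_membrane(
                hh_params, StimulusProgram.constant(irr, 20.0), record_dt=0.02
            )
            peak_times.append(traj.t[np.argmin(traj.V)])
        diffs = np.diff(peak_times)
        assert np.all(diffs <= 0.05)

    def test_subthreshold_irradiance_single_peak(self, hh_params):
        for irr in (4.0, 8.0, 12.0):
            _, trace = simulate_membrane(
                hh_params, StimulusProgram.constant(irr, 60.0)
            )
            assert count_hyperpolarization_events(trace) <= 1

    def test_ros_monotonicity(self, hh_params):
        """More ROS production brings the habituated plateau earlier and
        makes it at least as high; less ROS lengthens the quiescent gap."""
        from dataclasses import replace

        onsets, plateaus = [], []
        for alpha in (0.08, 0.1, 0.14):
            params = replace(hh_params, alpha_ROS=alpha)
            traj, _ = simulate_membrane(
                params, StimulusProgram.constant(20.0, 60.0)
            )
            late = traj.t > 15.0
            below = np.where(late & (traj.V < -100.0))[0]
            onsets.append(traj.t[below[0]] if below.size else np.inf)
            plateaus.append(-traj.V[-1])
        assert onsets[0] > onsets[1] > onsets[2]
        assert plateaus[0] <= plateaus[1] + 0.5 <= plateaus[2] + 1.0


class TestMembraneState:
    def test_gate_bounds_enforced(self):
        with pytest.raises(ValueError, match="m_Q"):
            MembraneState(t=0, V=-60, m_Q=1.5, h_Q=0.5, n_K=0.5, S=0)

    def test_resting_state_is_dark(self):
        params = HHParams()
        state = MembraneState.resting(params)
        assert state.V == params.E_L
        assert state.n_K < 0.05
        assert state.h_Q > 0.9


class TestStimulusProgram:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            StimulusProgram(schedule=((0, 10, 5.0), (5, 15, 5.0)),
                            total_duration=20.0)

    def test_irradiance_lookup(self):
        stim = StimulusProgram(schedule=((0, 5, 2.0), (10, 15, 4.0)),
                               total_duration=20.0)
        assert stim.irradiance_at(2.0) == 2.0
        assert stim.irradiance_at(7.0) == 0.0
        assert stim.irradiance_at(12.0) == 4.0
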