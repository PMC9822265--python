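"""Evoked-response measurement, classification and the E-I ratio."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecphys.recordings import ProtocolKind, StimulusProtocol
from ecphys.synaptic import (
    average_sweeps,
    baseline_vm,
    classify_response,
    condition_contrast,
    ei_ratio,
    measure_evoked,
    measure_train,
    paired_connectivity,
)
from ecphys.synth import (
    MembraneParams,
    PSPComponent,
    SynapseParams,
    simulate_evoked,
    simulate_membrane_events,
)

from conftest import make_sweep


def _pulse(onset=520.0):
    return StimulusProtocol(kind=ProtocolKind.OPTO_PULSE, onset_ms=onset,
                            parameters={"pulse_width_ms": 3.0})


def _train(freq=10.0, n_pulses=10, onset=1010.0):
    return StimulusProtocol(
        kind=ProtocolKind.OPTO_TRAIN, onset_ms=onset,
        parameters={"pulse_width_ms": 3.0, "frequency_hz": freq,
                    "n_pulses": n_pulses},
    )


class TestBaseline:
    def test_constant_trace(self):
        s = make_sweep(np.full(22001, -65.0), protocol=_pulse())
        assert baseline_vm(s) == pytest.approx(-65.0)

    def test_final_10ms_excluded(self):
        v = np.full(22001, -65.0)
        s = make_sweep(v, protocol=_pulse())
        i0 = s.index_at(511.0)
        i1 = s.index_at(519.0)
        v[i0:i1] = 0.0  # transient confined to the exclusion window
        assert baseline_vm(s) == pytest.approx(-65.0)

    def test_insufficient_prestimulus_span_rejected(self):
        s = make_sweep(np.full(8001, -65.0), protocol=_pulse(onset=300.0))
        with pytest.raises(ValueError, match="baseline"):
            baseline_vm(s)

    def test_train_window_is_990ms(self):
        v = np.full(50001, -65.0)
        s = make_sweep(v, protocol=_train())
        # transient confined to the 10 ms exclusion zone before the train
        v[s.index_at(1002.0):s.index_at(1008.0)] = 0.0
        assert baseline_vm(s) == pytest.approx(-65.0)

    def test_ou_baseline_estimator_variance(self):
        """SD of the 490 ms-window baseline estimate matches the analytic
        variance of an averaged OU process, 2 sd^2 tau / T."""
        p = MembraneParams(C_pF=150.0, g_L_nS=6.5, noise_sd_mV=0.3,
                           noise_tau_ms=5.0)
        vals = []
        for seed in range(100):
            sweeps, _ = simulate_evoked(
                p, SynapseParams(components={}), _pulse(), 1, seed=seed,
                duration_ms=600.0,
            )
            vals.append(baseline_vm(sweeps[0]))
        expected_sd = math.sqrt(2 * 0.3**2 * 5.0 / 490.0)
        assert np.std(vals) == pytest.approx(expected_sd, rel=0.35)


class TestAverageSweeps:
    def test_identical_sweeps_unchanged(self):
        s = make_sweep(np.linspace(-65, -60, 1000))
        avg = average_sweeps([s, s, s])
        np.testing.assert_allclose(avg.voltage, s.voltage)

    def test_mirror_pair_cancels(self):
        base = np.full(1000, -65.0)
        dev = np.sin(np.linspace(0, 6, 1000))
        a = make_sweep(base + dev)
        b = make_sweep(base - dev)
        np.testing.assert_allclose(average_sweeps([a, b]).voltage, base)

    def test_noise_reduction_follows_sqrt_n(self):
        rng = np.random.default_rng(0)
        sweeps = [make_sweep(-65.0 + rng.normal(0, 0.5, 4000)) for _ in range(30)]
        avg = average_sweeps(sweeps)
        assert np.std(avg.voltage) == pytest.approx(0.5 / math.sqrt(30), rel=0.15)

    def test_heterogeneous_sweeps_rejected(self):
        with pytest.raises(ValueError):
            average_sweeps([make_sweep(np.zeros(100)), make_sweep(np.zeros(200))])


class TestEIRatio:
    @pytest.mark.parametrize("e, i, expected", [(5, 5, 0.5), (5, 0, 1.0), (2, 6, 0.25)])
    def test_formula(self, e, i, expected):
        assert ei_ratio(e, i) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            ei_ratio(0.0, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        e=st.floats(0.0, 50.0),
        i=st.floats(0.0, 50.0),
    )
    def test_bounds_and_monotonicity(self, e, i):
        if e + i == 0:
            return
        r = ei_ratio(e, i)
        assert 0.0 <= r <= 1.0
        if i == 0.0:
            assert r == 1.0
        if e > 0:
            assert ei_ratio(e, i + 1.0) < r


class TestClassification:
    @pytest.mark.parametrize(
        "e, i, supra, expected",
        [
            (0.0, 0.0, False, "none"),
            (4.0, 3.0, False, "biphasic"),
            (4.0, 0.2, False, "excitatory"),
            (0.1, 2.0, False, "inhibitory"),
            (0.3, 0.3, False, "none"),  # both below the 0.5 mV floor
            (4.0, 3.0, True, "suprathreshold"),
        ],
    )
    def test_rules(self, e, i, supra, expected):
        assert classify_response(e, i, supra) == expected

    def test_floor_rises_with_baseline_noise(self):
        assert classify_response(0.8, 0.0, False, baseline_noise_sd=0.1) == "excitatory"
        assert classify_response(0.8, 0.0, False, baseline_noise_sd=0.4) == "none"


class TestMeasureEvoked:
    def test_single_epsp_recovered(self, rc_membrane, epsp_only):
        sweeps, _ = simulate_evoked(rc_membrane, epsp_only, _pulse(), 1, seed=0,
                                    duration_ms=1120.0)
        r = measure_evoked(sweeps)
        assert r.epsp_amp_mV == pytest.approx(5.0, abs=0.05)
        assert r.ipsp_amp_mV == 0.0
        assert r.classification == "excitatory"
        assert r.ei_ratio == pytest.approx(1.0)

    def test_symmetric_biphasic_has_balanced_ratio(self, rc_membrane):
        sp = SynapseParams(components={
            "epsp_fast": PSPComponent(4.0, 0.6, 8.0, latency_ms=2.0),
            "ipsp_slow": PSPComponent(-4.0, 50.0, 180.0, latency_ms=7.0),
        })
        sweeps, _ = simulate_evoked(rc_membrane, sp, _pulse(), 1, seed=0,
                                    duration_ms=1520.0)
        r = measure_evoked(sweeps)
        assert r.classification == "biphasic"
        assert r.ei_ratio == pytest.approx(0.5, abs=0.02)

    def test_small_response_has_no_latency_or_half_width(self, rc_membrane):
        sp = SynapseParams(components={
            "epsp_fast": PSPComponent(0.8, 0.6, 8.0, latency_ms=2.0)
        })
        sweeps, _ = simulate_evoked(rc_membrane, sp, _pulse(), 1, seed=0,
                                    duration_ms=1120.0)
        r = measure_evoked(sweeps)
        assert r.latency_ms is None and r.half_width_ms is None

    def test_latency_increases_with_synaptic_delay(self, rc_membrane):
        latencies = []
        for delay in (1.0, 2.0, 4.0):
            sp = SynapseParams(components={
                "epsp_fast": PSPComponent(5.0, 0.6, 8.0, latency_ms=delay)
            })
            sweeps, _ = simulate_evoked(rc_membrane, sp, _pulse(), 1, seed=0,
                                        duration_ms=1120.0)
            latencies.append(measure_evoked(sweeps).latency_ms)
        assert latencies[0] < latencies[1] < latencies[2]

    def test_suprathreshold_dominates(self):
        p = MembraneParams(C_pF=150.0, g_L_nS=6.5, noise_sd_mV=0.0)
        sp = SynapseParams(components={
            "epsp_fast": PSPComponent(30.0, 0.6, 8.0, latency_ms=2.0)
        })
        sweeps, _ = simulate_evoked(p, sp, _pulse(), 2, seed=0, duration_ms=1120.0)
        assert measure_evoked(sweeps).classification == "suprathreshold"


class TestMeasureTrain:
    def test_pulse_windows_at_20hz_are_50ms(self, rc_membrane):
        sp = SynapseParams(components={
            "epsp_fast": PSPComponent(4.0, 0.6, 8.0, latency_ms=2.0)
        })
        proto = _train(freq=20.0)
        sweeps, _ = simulate_evoked(rc_membrane, sp, proto, 1, seed=0,
                                    duration_ms=1010.0 + 10 * 50.0 + 200.0)
        tr = measure_train(sweeps)
        assert tr.n_pulses == 10
        # every pulse window catches its own kernel peak
        assert np.all(tr.epsp_amp_mV > 3.0)

    def test_constant_kernels_give_stable_amplitudes(self, rc_membrane):
        sp = SynapseParams(components={
            "epsp_fast": PSPComponent(4.0, 0.6, 8.0, latency_ms=2.0,
                                      train_scaling=(1.0,) * 10)
        })
        sweeps, _ = simulate_evoked(rc_membrane, sp, _train(), 1, seed=0,
                                    duration_ms=2300.0)
        tr = measure_train(sweeps)
        assert tr.epsp_amp_mV[9] == pytest.approx(tr.epsp_amp_mV[0], rel=0.05)

    def test_ipsp_growth_raises_ipsp_and_lowers_ei(self, rc_membrane):
        growth = tuple(np.linspace(1.0, 1.6, 10))
        sp = SynapseParams(components={
            "epsp_fast": PSPComponent(4.0, 0.6, 8.0, latency_ms=2.0,
                                      train_scaling=(1.0,) * 10),
            "ipsp_fast": PSPComponent(-3.0, 2.0, 15.0, latency_ms=3.5,
                                      train_scaling=growth),
        })
        sweeps, _ = simulate_evoked(rc_membrane, sp, _train(), 1, seed=0,
                                    duration_ms=2300.0)
        tr = measure_train(sweeps)
        assert tr.ipsp_amp_mV[9] > tr.ipsp_amp_mV[0]
        assert tr.ei_ratio[9] < tr.ei_ratio[0]

    def test_window_past_sweep_end_rejected(self, rc_membrane):
        sp = SynapseParams(components={
            "epsp_fast": PSPComponent(4.0, 0.6, 8.0, latency_ms=2.0)
        })
        sweeps, _ = simulate_evoked(rc_membrane, sp, _train(), 1, seed=0,
                                    duration_ms=1950.0)
        with pytest.raises(ValueError, match="past the end"):
            measure_train(sweeps)


class TestPairedRecordings:
    @pytest.fixture
    def pre_sweep(self):
        p = MembraneParams(C_pF=80.0, g_L_nS=8.0, E_L_mV=-62.0, noise_sd_mV=0.0)
        proto = StimulusProtocol(
            kind=ProtocolKind.PAIRED_AP, onset_ms=600.0,
            parameters={"amplitude_pA": 1500.0, "pulse_width_ms": 3.0},
        )
        sweep, spikes = simulate_membrane_events(p, proto, 1200.0, seed=0,
                                                 cell_id="pre")
        assert len(spikes) >= 1
        return sweep

    def _post(self, components, seed=1):
        p = MembraneParams(C_pF=150.0, g_L_nS=6.5, noise_sd_mV=0.1)
        proto = StimulusProtocol(kind=ProtocolKind.OPTO_PULSE, onset_ms=601.0,
                                 parameters={"pulse_width_ms": 0.0})
        sweeps, _ = simulate_evoked(
            p, SynapseParams(components=components), proto, 10, seed=seed,
            duration_ms=1200.0, cell_id="post",
        )
        return sweeps

    def test_connected_pair_recovers_amplitude(self, pre_sweep):
        post = self._post({"ipsp_fast": PSPComponent(-1.5, 2.0, 15.0, 1.5)})
        res = paired_connectivity(pre_sweep, post)
        assert res.connected
        assert res.ipsp_amp_mV == pytest.approx(1.5, abs=0.1)

    def test_unconnected_pair(self, pre_sweep):
        res = paired_connectivity(pre_sweep, self._post({}))
        assert not res.connected

    def test_two_component_ipsp_has_wider_half_width(self, pre_sweep):
        fast_only = paired_connectivity(
            pre_sweep, self._post({"ipsp_fast": PSPComponent(-1.5, 2.0, 15.0, 1.5)})
        )
        both = paired_connectivity(
            pre_sweep,
            self._post({
                "ipsp_fast": PSPComponent(-1.5, 2.0, 15.0, 1.5),
                "ipsp_slow": PSPComponent(-1.0, 50.0, 180.0, 4.0),
            }),
        )
        assert both.half_width_ms > fast_only.half_width_ms

    def test_no_presynaptic_spike_rejected(self):
        flat = make_sweep(np.full(24001, -62.0), cell_id="pre")
        with pytest.raises(ValueError, match="action potential"):
            paired_connectivity(flat, [make_sweep(np.full(24001, -65.0))])


class TestConditionContrast:
    def _response(self, cell, cond, hw):
        from ecphys.synaptic import EvokedResponse

        return EvokedResponse(
            cell_id=cell, condition=cond, baseline_vm_mV=-65.0,
            epsp_amp_mV=4.0, ipsp_amp_mV=1.0, classification="biphasic",
            ei_ratio=0.8, latency_ms=3.0, half_width_ms=hw, n_sweeps_averaged=10,
        )

    def test_long_table_shape(self):
        data = {
            cond: {f"c{i}": self._response(f"c{i}", cond, 20.0) for i in range(5)}
            for cond in ("baseline", "gabazine", "cgp")
        }
        table = condition_contrast(data)
        assert len(table) == 5 * 3 * 3  # cells x conditions x features

    def test_identical_conditions_have_zero_differences(self):
        data = {
            cond: {f"c{i}": self._response(f"c{i}", cond, 20.0) for i in range(4)}
            for cond in ("a", "b")
        }
        table = condition_contrast(data)
        wide = table.pivot_table(index=["cell_id", "feature"], columns="condition",
                                 values="value")
        assert (wide["a"] == wide["b"]).all()

    def test_blocking_fast_inhibition_widens_epsp(self, rc_membrane):
        """Removing the GABA_A-like kernel increases the measured EPSP
        half-width in every noiseless cell."""
        wider = 0
        for i in range(5):
            rng = np.random.default_rng(i)
            comps = {
                "epsp_fast": PSPComponent(float(rng.uniform(2, 6)), 0.6, 8.0, 2.0),
                "ipsp_fast": PSPComponent(-2.0, 2.0, 15.0, 3.5),
                "ipsp_slow": PSPComponent(-1.0, 50.0, 180.0, 7.0),
            }
            base, _ = simulate_evoked(rc_membrane, SynapseParams(components=comps),
                                      _pulse(), 1, seed=i, duration_ms=1120.0)
            no_fast = {k: v for k, v in comps.items() if k != "ipsp_fast"}
            gbz, _ = simulate_evoked(rc_membrane, SynapseParams(components=no_fast),
                                     _pulse(), 1, seed=i, duration_ms=1120.0)
            wider += (measure_evoked(gbz).half_width_ms
                      > measure_evoked(base).half_width_ms)
        assert wider == 5

    def test_disjoint_cells_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            condition_contrast({
                "a": {"c1": self._response("c1", "a", 20.0)},
                "b": {"c2": self._response("c2", "b", 20.0)},
            })
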