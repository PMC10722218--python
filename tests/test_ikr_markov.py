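"""Markov-chain I_Kr model: rates, occupancy dynamics, current, clamp."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herglqt.errors import InvalidInputError
from herglqt.ikr_markov import (
    ClampProtocol,
    Genotype,
    MCParams,
    MCState,
    advance_occupancy,
    build_generator,
    ikr_current,
    run_voltage_clamp,
    steady_state_occupancy,
    transition_rates,
    traces_from_csv,
    traces_to_csv,
)
from herglqt.synthetic_clamp import default_true_params, standard_protocol


def make_params(a=None, b=None, g=0.1, genotype="WT"):
    return MCParams(
        a=np.full(8, 0.1) if a is None else np.asarray(a, float),
        b=np.zeros(8) if b is None else np.asarray(b, float),
        g_kr=g,
        genotype=genotype,
    )


class TestTransitionRates:
    def test_voltage_independent_limit_and_v0(self):
        p = make_params(a=np.linspace(0.01, 0.08, 8))
        for V in (-80.0, 0.0, 55.0):
            r = transition_rates(V, p)
            assert np.allclose(list(r.values()), p.a)

    def test_closed_form_value(self):
        p = make_params(a=np.full(8, 0.1), b=np.full(8, 0.01))
        r = transition_rates(20.0, p)
        assert np.allclose(list(r.values()), 0.1 * np.exp(0.2))

    def test_invalid_inputs_rejected(self):
        p = make_params()
        with pytest.raises(InvalidInputError):
            transition_rates(np.nan, p)
        with pytest.raises(InvalidInputError):
            MCParams(a=np.zeros(8), b=np.zeros(8), g_kr=0.1)
        with pytest.raises(InvalidInputError):
            MCParams(a=np.full(8, 0.1), b=np.full(8, np.nan), g_kr=0.1)


class TestOccupancyDynamics:
    def test_dt_zero_is_identity(self):
        s = MCState(0.2, 0.2, 0.2, 0.2, 0.2)
        assert advance_occupancy(s, -20.0, 0.0, make_params()) is s

    def test_symmetric_chain_relaxes_to_uniform(self):
        p = make_params(a=np.full(8, 0.1))
        ss = steady_state_occupancy(0.0, p)
        assert np.allclose(ss.as_array(), 0.2, atol=1e-12)

    def test_absorbing_direction_limit(self):
        a = np.full(8, 0.1)
        a[6] = 1e-9  # O -> I essentially closed, I -> O open
        ss = steady_state_occupancy(0.0, make_params(a=a))
        assert ss.i < 1e-6

    def test_long_hold_matches_nullspace_oracle(self):
        # hold long enough to outlast the slowest (activation) eigenmode,
        # which has a time constant of order seconds near -20 mV
        p = default_true_params("WT")
        s = MCState.resting()
        out = advance_occupancy(s, -20.0, 60_000.0, p)
        ss = steady_state_occupancy(-20.0, p)
        assert np.max(np.abs(out.as_array() - ss.as_array())) < 1e-6

    @pytest.mark.parametrize("V", np.linspace(-80, 60, 20))
    def test_oracle_equivalence_across_voltages(self, V):
        """Long-time integration agrees with the stationary null-space solve."""
        p = default_true_params("WT")
        out = advance_occupancy(MCState.resting(), V, 60_000.0, p)
        ss = steady_state_occupancy(V, p)
        assert np.max(np.abs(out.as_array() - ss.as_array())) < 1e-6

    def test_conservation_and_nonnegativity_over_many_steps(self):
        p = default_true_params("WT")
        s = MCState.resting()
        rng = np.random.default_rng(0)
        volts = rng.uniform(-80, 40, 2000)
        for V in volts:
            s = advance_occupancy(s, V, 0.02, p)
        pi = s.as_array()
        assert abs(pi.sum() - 1.0) < 1e-9
        assert np.all(pi > -1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(InvalidInputError):
            advance_occupancy(MCState.resting(), 0.0, -1.0, make_params())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        loga=st.lists(st.floats(-6, 1), min_size=8, max_size=8),
        b=st.lists(st.floats(-0.08, 0.08), min_size=8, max_size=8),
        V=st.floats(-90, 60),
    )
    def test_stationarity_property(self, loga, b, V):
        """pi Q = 0 and sum(pi) = 1 for arbitrary admissible rate sets."""
        p = make_params(a=np.exp(loga), b=np.array(b))
        ss = steady_state_occupancy(V, p)
        pi = ss.as_array()
        assert abs(pi.sum() - 1.0) < 1e-9
        assert np.all(pi >= 0)
        assert np.max(np.abs(pi @ build_generator(V, p))) < 1e-10


class TestCurrent:
    def test_zero_driving_force_and_closed_channel(self):
        p = make_params(g=0.5)
        assert ikr_current(MCState(0, 0, 0, 1.0, 0), -88.0, p, EK=-88.0) == 0.0
        assert ikr_current(MCState(1.0, 0, 0, 0.0, 0), 0.0, p, EK=-88.0) == 0.0

    def test_closed_form_value(self):
        p = make_params(g=0.153)
        s = MCState(0.0, 0.0, 0.0, 1.0, 0.0)
        assert ikr_current(s, -38.0, p, Ko=5.4, EK=-88.0) == pytest.approx(7.65)

    def test_hom_genotype_forces_zero(self):
        p = make_params(g=0.5, genotype="HOM")
        s = MCState(0.0, 0.0, 0.0, 1.0, 0.0)
        assert ikr_current(s, 0.0, p) == 0.0

    def test_bad_ko_rejected(self):
        with pytest.raises(InvalidInputError):
            ikr_current(MCState.resting(), 0.0, make_params(), Ko=0.0)


class TestVoltageClamp:
    def test_zero_conductance_gives_flat_traces(self):
        p = default_true_params("WT").with_conductance(0.0)
        res = run_voltage_clamp(p, standard_protocol())
        for tr in res.traces:
            assert np.all(tr.current_pApF == 0.0)
        assert np.all(res.iv_peak_tail.current == 0.0)

    def test_trace_length_bookkeeping(self):
        prot = standard_protocol()
        res = run_voltage_clamp(default_true_params("WT"), prot)
        n_expected = int(round(prot.sweep_duration_ms / prot.sample_interval_ms)) + 1
        assert len(res.traces) == len(prot.step_voltages)
        for tr in res.traces:
            assert tr.time_ms.size == n_expected

    def test_generator_round_trip_iv(self, wt_dataset):
        """Re-simulating the generator's truth reproduces its reference I-V."""
        res = run_voltage_clamp(wt_dataset.true_params, wt_dataset.protocol)
        assert np.max(np.abs(res.iv_peak_tail.current
                             - wt_dataset.noiseless.iv_peak_tail.current)) < 1e-8

    def test_protocol_validation(self):
        with pytest.raises(InvalidInputError):
            ClampProtocol(holding_mV=-80, segments=((-80, 100.0), (None, -5.0)),
                          step_voltages=(0.0,))
        with pytest.raises(InvalidInputError):
            ClampProtocol(holding_mV=-80, segments=((-80, 100.0),),
                          step_voltages=(0.0,))  # no variable segment

    def test_trace_csv_round_trip(self, tmp_path, wt_dataset):
        path = tmp_path / "traces.csv"
        traces_to_csv(wt_dataset.noiseless.traces, path)
        back = traces_from_csv(path)
        assert len(back) == len(wt_dataset.noiseless.traces)
        orig = {t.sweep_mV: t for t in wt_dataset.noiseless.traces}
        for tr in back:
            assert np.allclose(tr.current_pApF, orig[tr.sweep_mV].current_pApF)
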