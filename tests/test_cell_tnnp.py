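"""Ventricular cell model: stability, AP morphology, APD, restitution."""

import numpy as np
import pytest

from herglqt.cell_tnnp import (
    CellConfig,
    CellState,
    PacingProtocol,
    RestitutionResult,
    max_restitution_slope,
    measure_apd90,
    pace_to_steady_state,
    restitution,
    resting_state,
    simulate_beat,
    steady_state_cell,
)
from herglqt.errors import ConfigurationError, MeasurementError
from herglqt.ikr_markov import MCParams
from herglqt.synthetic_clamp import default_true_params


def cfg_for(ct="EPI", gt="WT", **kw):
    return CellConfig(cell_type=ct, genotype=gt,
                      mc_params=default_true_params(gt), **kw)


class TestStepping:
    def test_resting_stability(self):
        """An unstimulated cell at its quiescent equilibrium stays put."""
        from herglqt.cell_tnnp import _run_interval

        cfg = cfg_for()
        rest = resting_state(cfg)
        S = rest.y.reshape(1, -1).copy()
        rec = _run_interval(S, cfg, 1000.0, None, cfg.tables())
        assert np.max(np.abs(rec.V - rec.V[0])) < 0.01

    def test_paced_beat_morphology(self):
        """One 1 Hz beat: overshoot +20..+50 mV, fast upstroke (>100 mV/ms)."""
        cfg = cfg_for()
        state, hist = steady_state_cell(cfg)
        _, rec = simulate_beat(state, cfg, 1000.0)
        m = hist[-1]
        assert 20.0 < m.v_peak < 50.0
        assert m.dvdt_max > 100.0
        assert -90.0 < m.v_rest < -80.0

    def test_hom_equals_wt_with_zero_conductance(self):
        """Hard-zero HOM current and g_kr = 0 produce identical voltage paths."""
        hom = CellConfig(cell_type="EPI", genotype="HOM",
                         mc_params=default_true_params("HOM"))
        wt0 = CellConfig(cell_type="EPI", genotype="WT",
                         mc_params=default_true_params("WT").with_conductance(0.0))
        _, rec_h = simulate_beat(CellState.initial(hom), hom, 500.0)
        _, rec_w = simulate_beat(CellState.initial(wt0), wt0, 500.0)
        assert np.max(np.abs(rec_h.V - rec_w.V)) < 1e-9

    def test_tp2006_variant_not_available(self):
        with pytest.raises(ConfigurationError):
            CellConfig(model_variant="TP2006", ikr_formulation="hh")


class TestMeasureAPD90:
    def test_square_pulse(self):
        dt = 1.0
        w = 200
        V = np.full(400, -85.0)
        V[10:10 + w] = 40.0
        t = dt * np.arange(V.size)
        assert measure_apd90(t, V) == pytest.approx(w, abs=dt)

    def test_linear_repolarization_triangle(self):
        t = np.arange(0.0, 400.0, 1.0)
        V = np.full(t.size, -85.0)
        V[10] = 40.0
        ramp = np.linspace(40.0, -85.0, 301)
        V[10:311] = ramp
        assert measure_apd90(t, V) == pytest.approx(0.9 * 300.0, abs=1.0)

    def test_no_upstroke_raises(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(MeasurementError):
            measure_apd90(t, np.full(t.size, -85.0))


class TestSteadyStateAPD:
    def test_genotype_ordering(self, steady_apd):
        """Loss of I_Kr prolongs APD: WT < HET < HOM in every cell type."""
        for ct in ("ENDO", "MIDDLE", "EPI"):
            assert steady_apd[(ct, "WT")] < steady_apd[(ct, "HET")] < steady_apd[(ct, "HOM")]

    def test_apd_monotone_in_gkr_multiplier(self):
        """APD90 decreases as the I_Kr conductance multiplier grows."""
        apds = []
        for mult in (0.0, 0.36, 0.5, 1.0, 1.3, 2.0):
            cfg = CellConfig(cell_type="EPI", genotype="WT",
                             mc_params=default_true_params("WT"), gkr_multiplier=mult)
            _, hist = steady_state_cell(cfg)
            apds.append(hist[-1].apd90)
        assert all(a > b for a, b in zip(apds, apds[1:]))

    def test_dt_halving_changes_apd_below_1ms(self):
        a = {}
        for dt in (0.02, 0.01):
            cfg = cfg_for(dt=dt)
            _, hist = steady_state_cell(cfg)
            a[dt] = hist[-1].apd90
        assert abs(a[0.02] - a[0.01]) < 1.0


class TestRestitution:
    @pytest.fixture(scope="class")
    def rest_curves(self):
        out = {}
        # shortest interval kept above the HOM MIDDLE APD so both genotypes
        # capture a full (if premature) action potential at every point
        si = np.array([900.0, 800.0, 700.0, 600.0, 500.0, 440.0, 400.0])
        for gt in ("WT", "HOM"):
            cfg = cfg_for(ct="MIDDLE", gt=gt)
            out[gt] = restitution(cfg, si)
        return out

    def test_large_si_recovers_steady_apd(self, rest_curves, steady_apd):
        res = rest_curves["WT"]
        assert res.apd_a[0] == pytest.approx(steady_apd[("MIDDLE", "WT")], abs=2.0)

    def test_mutant_curve_above_wt(self, rest_curves):
        wt, hom = rest_curves["WT"], rest_curves["HOM"]
        both = np.isfinite(wt.apd_a) & np.isfinite(hom.apd_a)
        assert np.all(hom.apd_a[both] > wt.apd_a[both])

    def test_slope_trivial_cases(self):
        si = np.array([300.0, 250.0, 200.0, 150.0])
        flat = RestitutionResult(si, np.full(4, 250.0), np.full(4, 250.0),
                                 np.zeros(4, bool), None, np.nan)
        assert max_restitution_slope(flat) == 0.0
        lin = RestitutionResult(si, 100.0 + 0.5 * si, 100.0 + 0.5 * si,
                                np.zeros(4, bool), None, np.nan)
        assert max_restitution_slope(lin) == pytest.approx(0.5, abs=1e-6)

    def test_restitution_slope_positive(self, rest_curves):
        assert rest_curves["WT"].max_slope > 0.0
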