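"""Transmural strand: regions, propagation, pseudo-ECG, S2 classification."""

import numpy as np
import pytest

from herglqt.errors import ConfigurationError, InvalidInputError, MeasurementError
from herglqt.strand1d import (
    ECGTrace,
    S2Outcome,
    StrandConfig,
    StrandHistory,
    Stimulus,
    activation_times,
    classify_s2,
    conditioned_state,
    ecg_to_csv,
    measure_cv,
    measure_qt,
    pseudo_ecg,
    region_map,
    save_history_h5,
    simulate_strand,
)
from herglqt.synthetic_clamp import default_true_params


@pytest.fixture(scope="module")
def wt_cfg():
    return StrandConfig(genotype="WT", mc_params=default_true_params("WT"))


class TestConfig:
    def test_region_map_proportions(self, wt_cfg):
        """1 : 1.3 : 1 over 140 nodes -> ENDO 42, MIDDLE 55, EPI 43."""
        ct = region_map(wt_cfg)
        assert ct.size == 140
        assert np.sum(ct == 0) == 42 and np.sum(ct == 1) == 55 and np.sum(ct == 2) == 43
        assert ct[0] == 0 and ct[-1] == 2  # ENDO at stimulated end

    def test_cfl_violation_rejected(self):
        with pytest.raises(ConfigurationError):
            StrandConfig(genotype="HOM", dx_mm=0.05, dt=0.02, D=0.18)

    def test_node_count(self, wt_cfg):
        assert wt_cfg.n_nodes == round(wt_cfg.length_mm / wt_cfg.dx_mm) == 140


class TestPropagation:
    def test_no_stimulus_stays_at_rest(self, wt_cfg):
        """An unstimulated strand settles and then holds its resting profile."""
        from herglqt.strand1d import initial_strand_array

        S0 = initial_strand_array(wt_cfg, init="resting")
        settle = simulate_strand(wt_cfg, [], 2000.0, rec_every_ms=100.0, S0=S0)
        h = simulate_strand(wt_cfg, [], 1000.0, rec_every_ms=1.0, S0=settle.S)
        assert np.max(np.abs(h.V - h.V[0:1, :])) < 0.01

    def test_activation_monotone_with_node_index(self, strand_runs):
        h, _ = strand_runs["WT"]
        act = activation_times(h)
        assert np.all(np.isfinite(act))
        assert np.all(np.diff(act) > 0)

    def test_zero_diffusion_decouples_nodes(self):
        """With D = 0, a stimulated node fires; its neighbour never does."""
        cfg = StrandConfig(genotype="WT", mc_params=default_true_params("WT"), D=0.0)
        h = simulate_strand(cfg, [Stimulus(0.0, 0, 4)], 400.0, rec_every_ms=0.5)
        act = activation_times(h)
        assert np.all(np.isfinite(act[:5]))
        assert np.all(~np.isfinite(act[5:]))

    def test_stimulus_outside_grid_rejected(self, wt_cfg):
        with pytest.raises(InvalidInputError):
            simulate_strand(wt_cfg, [Stimulus(0.0, 0, 200)], 10.0)


class TestCV:
    def test_time_rescaled_history_halves_cv(self, strand_runs):
        h, _ = strand_runs["WT"]
        cv = measure_cv(h)
        slowed = StrandHistory(2.0 * h.time_ms, h.V, h.S, h.config)
        assert measure_cv(slowed) == pytest.approx(cv / 2.0, rel=1e-9)

    def test_cv_scales_like_sqrt_of_diffusion(self):
        """Cable theory: CV ratio for D x4 is ~2."""
        cvs = {}
        for D in (0.18, 0.72):
            cfg = StrandConfig(genotype="WT", mc_params=default_true_params("WT"),
                               D=D, dt=0.01)
            S = conditioned_state(cfg)
            h = simulate_strand(cfg, [Stimulus(0.0, 0, 4)], 120.0,
                                rec_every_ms=0.05, S0=S)
            cvs[D] = measure_cv(h)
        assert cvs[0.72] / cvs[0.18] == pytest.approx(2.0, rel=0.15)


class TestPseudoECG:
    def test_uniform_field_gives_zero(self, wt_cfg):
        h = StrandHistory(np.arange(10.0), np.full((10, 140), -30.0),
                          np.zeros((140, 22)), wt_cfg)
        ecg = pseudo_ecg(h)
        assert np.allclose(ecg.phi, 0.0)

    def test_sign_flip_linearity(self, strand_runs):
        h, ecg = strand_runs["WT"]
        flipped = StrandHistory(h.time_ms, -h.V, h.S, h.config)
        ecg2 = pseudo_ecg(flipped)
        assert np.allclose(ecg2.phi, -ecg.phi)

    def test_wt_t_wave_positive(self, strand_runs):
        """EPI (electrode side) repolarises before MIDDLE -> upright T wave."""
        _, ecg = strand_runs["WT"]
        late = ecg.time_ms > 150.0
        k = np.argmax(np.abs(ecg.phi[late]))
        assert ecg.phi[late][k] > 0.0

    def test_electrode_inside_tissue_rejected(self, strand_runs):
        h, _ = strand_runs["WT"]
        with pytest.raises(InvalidInputError):
            pseudo_ecg(h, electrode_mm=-1.0)

    def test_qt_ordering_by_genotype(self, strand_runs):
        qts = {gt: measure_qt(ecg).qt_ms for gt, (_, ecg) in strand_runs.items()}
        assert qts["WT"] < qts["HET"] < qts["HOM"]

    def test_flat_trace_raises(self):
        with pytest.raises(MeasurementError):
            measure_qt(ECGTrace(np.arange(500.0), np.zeros(500)))

    def test_ecg_csv(self, tmp_path, strand_runs):
        _, ecg = strand_runs["WT"]
        ecg_to_csv(ecg, tmp_path / "e.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "e.csv")
        assert list(df.columns) == ["time_ms", "phi"]
        assert len(df) == ecg.phi.size


class TestS2Classification:
    @pytest.fixture(scope="class")
    def base(self, wt_cfg):
        return conditioned_state(wt_cfg)

    def test_short_delay_blocks_bidirectionally(self, wt_cfg, base):
        assert classify_s2(wt_cfg, 150.0, base) is S2Outcome.BIDIRECTIONAL_BLOCK

    def test_long_delay_conducts_bidirectionally(self, wt_cfg, base):
        assert classify_s2(wt_cfg, 450.0, base) is S2Outcome.BIDIRECTIONAL_CONDUCTION

    def test_history_h5_round_trip(self, tmp_path, strand_runs):
        import h5py

        h, _ = strand_runs["WT"]
        save_history_h5(h, tmp_path / "h.h5")
        with h5py.File(tmp_path / "h.h5") as f:
            assert f["V"].shape == h.V.shape
            assert f.attrs["genotype"] == "WT"
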