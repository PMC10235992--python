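"""Simulator unit and property tests: control-model oracles, steady-state
rates, detection emulation and determinism."""
import numpy as np
import pandas as pd
import pytest

from replicycle import simulate as sim
from replicycle import stats as st


def test_noise_free_adder_is_a_deterministic_fixed_point():
    cfg = sim.SimConfig(control_model="adder", delta_cv=0.0,
                        growth_rate_cv=0.0, division_fraction_sd=0.0,
                        division_timing_sd=0.0, C_period_cv=0.0,
                        n_lineages=3, n_generations=3, seed=0)
    _, truth = sim.simulate_lineages(cfg, frames=False)
    init = truth[truth.event_type == "initiation"]
    per_origin = init.area_um2 / init.n_origins_initiated
    assert np.allclose(per_origin, 2 * cfg.delta_mean, atol=1e-9)


@pytest.mark.parametrize("model,seed", [("sizer", 31), ("adder", 32),
                                        ("fluxbalance", 33)])
def test_steady_state_one_initiation_per_origin_per_generation(model, seed):
    """All three control models settle to one new round per origin per
    generation, within 3 SEM over >= 5,000 recorded generations."""
    n_lin = 60 if model == "fluxbalance" else 100
    cfg = sim.SimConfig(control_model=model, n_lineages=n_lin,
                        n_generations=4, burnin_generations=3, seed=seed)
    _, truth = sim.simulate_lineages(cfg, frames=False)
    rec = truth[truth.generation >= 0]
    n_gen = (rec.event_type == "division").sum()
    assert n_gen >= 5000
    rates = []
    for _, grp in rec.groupby("lineage_id"):
        fired = grp.loc[grp.event_type == "initiation",
                        "n_origins_initiated"].sum()
        born = grp.loc[grp.event_type == "division",
                       "n_origins_initiated"].sum() / 2.0
        rates.append(fired / born)
    rates = np.asarray(rates)
    sem = rates.std(ddof=1) / np.sqrt(len(rates))
    assert abs(rates.mean() - 1.0) <= 3 * max(sem, 1e-4)


def test_adder_consecutive_size_correlation_is_one_half(adder_truth):
    """Per-origin adder: Pearson correlation of consecutive initiation sizes
    is 1/2 (AR(1) with decay 1/2)."""
    _, truth = adder_truth
    p = st.consecutive_initiation_pairs(truth)
    assert len(p) >= 10_000
    rho = np.corrcoef(p.x, p.y)[0, 1]
    assert abs(rho - 0.5) <= 0.03


def test_sizer_consecutive_size_correlation_is_zero(sizer_truth):
    _, truth = sizer_truth
    p = st.consecutive_initiation_pairs(truth)
    assert len(p) >= 10_000
    rho = np.corrcoef(p.x, p.y)[0, 1]
    assert abs(rho) <= 0.03


def test_adder_stationary_variance_ratio(adder_truth):
    """Var(initiation size) / Var(delta * O) = 4/3 for the per-origin adder."""
    cfg, truth = adder_truth
    init = truth[(truth.event_type == "initiation")
                 & (truth.generation >= 0)
                 & (truth.n_origins_initiated == 1)]
    var_delta = (cfg.delta_mean * cfg.delta_cv) ** 2
    ratio = init.area_um2.var() / var_delta
    assert ratio == pytest.approx(4.0 / 3.0, rel=0.05)


def test_division_fractions_conserve_area():
    """Sister dfrac values sum to 1, so daughter areas partition the parent
    area exactly at the division instant."""
    cfg = sim.SimConfig(n_lineages=5, n_generations=3, seed=4)
    cells, _ = sim.simulate_lineages(cfg)
    per_cell = cells.drop_duplicates("cell_id").set_index("cell_id")
    checked = 0
    for cid, row in per_cell.iterrows():
        sid = row["sister_id"]
        if isinstance(sid, str) and sid in per_cell.index:
            assert row["dfrac"] + per_cell.loc[sid, "dfrac"] == \
                pytest.approx(1.0, abs=1e-9)
            checked += 1
    assert checked > 10


def test_seed_determinism_byte_identical():
    cfg = sim.SimConfig(n_lineages=3, n_generations=3, seed=99)
    c1, t1 = sim.simulate_lineages(cfg)
    c2, t2 = sim.simulate_lineages(sim.SimConfig(n_lineages=3,
                                                 n_generations=3, seed=99))
    assert c1.to_csv(index=False) == c2.to_csv(index=False)
    assert t1.to_csv(index=False) == t2.to_csv(index=False)
    d1 = sim.emulate_detections(c1, t1, sim.ImagingConfig(), seed=5)
    d2 = sim.emulate_detections(c2, t2, sim.ImagingConfig(), seed=5)
    assert d1.to_csv(index=False) == d2.to_csv(index=False)


def test_dnaA_fold_change_values():
    assert sim.dnaA_fold_change(100.0, 100.0, 60.0, 1.0) == 1.0
    # two halvings after turn-off
    assert sim.dnaA_fold_change(220.0, 100.0, 60.0, 1.0) == \
        pytest.approx(0.25, abs=1e-12)
    # over-expressed start: 8 * 2^-3 = 1
    assert sim.dnaA_fold_change(280.0, 100.0, 60.0, 8.0) == \
        pytest.approx(1.0, abs=1e-12)
    # constant before turn-off
    assert sim.dnaA_fold_change(10.0, 100.0, 60.0, 8.0) == 8.0


class TestEmulateDetections:
    def _one_round_setup(self, n_ori=1):
        cells = pd.DataFrame({
            "cell_id": ["a"] * 5, "lineage_id": [0] * 5,
            "frame": range(5), "time_min": [0.0, 2, 4, 6, 8],
            "area_um2": [2.0] * 5, "length_um": [2.0] * 5,
            "x_low_um": [0.0] * 5, "x_high_um": [2.0] * 5,
            "parent_id": [""] * 5, "sister_id": [""] * 5,
            "dfrac": [0.5] * 5, "qc_ok": [1] * 5,
        })
        truth = pd.DataFrame({
            "lineage_id": [0, 0], "cell_id": ["a", "a"],
            "event_type": ["initiation", "termination"],
            "time_min": [0.0, 100.0], "true_supercell_area": [2.0, 2.0],
            "n_origins_initiated": [n_ori, n_ori], "depth": [0, 0],
            "round_id": ["r0", "r0"], "area_um2": [2.0, 2.0],
            "super_scale": [1.0, 1.0], "parent_cell_id": ["", ""],
            "dfrac": [0.5, 0.5], "generation": [0, 0],
        })
        return cells, truth

    def test_one_round_midcell_exact(self):
        cells, truth = self._one_round_setup()
        img = sim.ImagingConfig(detection_prob=1.0, position_jitter_sd=0.0,
                                false_positive_rate=0.0)
        det = sim.emulate_detections(cells, truth, img, seed=1)
        assert len(det) == 5  # one per frame
        assert np.allclose(det.pos_in_cell_um, 0.0)

    def test_two_rounds_at_quarter_positions(self):
        cells, truth = self._one_round_setup(n_ori=2)
        img = sim.ImagingConfig(detection_prob=1.0, position_jitter_sd=0.0,
                                false_positive_rate=0.0)
        det = sim.emulate_detections(cells, truth, img, seed=1)
        assert len(det) == 10
        pos = np.sort(det.pos_in_cell_um.unique())
        assert np.allclose(pos, [-0.5, 0.5])  # +/- L/4 with L = 2 µm

    def test_zero_detection_prob_empty(self):
        cells, truth = self._one_round_setup()
        img = sim.ImagingConfig(detection_prob=0.0, false_positive_rate=0.0)
        det = sim.emulate_detections(cells, truth, img, seed=1)
        assert det.empty


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        sim.SimConfig(control_model="timer").validated()
    with pytest.raises(ValueError):
        sim.SimConfig(division_fraction_sd=0.5).validated()
    with pytest.raises(ValueError):
        sim.SimConfig(C_period=-1.0).validated()
    with pytest.raises(ValueError):
        sim.ImagingConfig(detection_prob=1.5).validated()
    with pytest.raises(ValueError):
        sim.DilutionScenario(exponent_a=-0.1).validated()


def test_fluxbalance_bad_substep_reported():
    """A too-coarse Euler substep that drives the activity negative raises
    instead of silently clipping."""
    cfg = sim.SimConfig(control_model="fluxbalance", k_off=50.0, dt_sub=40.0,
                        n_lineages=1, n_generations=2, seed=0)
    with pytest.raises(sim.FluxBalanceIntegrationError):
        sim.simulate_lineages(cfg, frames=False)
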