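"""Correlation-statistics tests: pairing, cluster selection, the bivariate
Gaussian + background fit, partial correlation, and the dilution analysis."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from replicycle import simulate as sim
from replicycle import stats as st


def events_df(rows):
    """rows: (event_type, supercell_id, supercell_area, round_index)."""
    return pd.DataFrame(rows, columns=["event_type", "supercell_id",
                                       "supercell_area", "round_index"])


class TestPairEvents:
    def test_single_initiation_termination_pair(self):
        df = events_df([("initiation", 0, 1.0, 0), ("termination", 0, 1.5, 0)])
        sc = st.pair_events(df, "I-T")
        assert len(sc.data) == 1
        assert sc.data.offset.iloc[0] == 0

    def test_three_initiations_ordered_pairs(self):
        df = events_df([("initiation", 0, 1.0, 0), ("initiation", 0, 2.0, 1),
                        ("initiation", 0, 4.0, 2)])
        sc = st.pair_events(df, "I-I")
        assert len(sc.data) == 3
        assert sorted(sc.data.offset) == [1, 1, 2]

    def test_pairs_stay_within_supercell(self):
        df = events_df([("initiation", 0, 1.0, 0), ("initiation", 1, 2.0, 0)])
        sc = st.pair_events(df, "I-I")
        assert sc.data.empty

    def test_termination_next_initiation_offset(self):
        df = events_df([("termination", 0, 1.5, 0), ("initiation", 0, 1.0, 0),
                        ("initiation", 0, 2.0, 1)])
        sc = st.pair_events(df, "T-I")
        assert sorted(sc.data.offset) == [0, 1]


class TestSelectCluster:
    def _three_cluster_scatter(self):
        """Three initiation rounds per supercell at ~1, ~2 and ~4 µm², the
        last sitting against the supercell span edge (span 0.8-4.2)."""
        rng = np.random.default_rng(5)
        rows = []
        for sc_id in range(300):
            sizes = [1.0 + 0.08 * rng.standard_normal()]
            sizes.append(sizes[0] + 1.0 + 0.15 * rng.standard_normal())
            sizes.append(sizes[1] + 2.0 + 0.1 * rng.standard_normal())
            for i, x in enumerate(sizes):
                rows.append(("initiation", sc_id, x, i, 0.8, 4.2))
        df = pd.DataFrame(rows, columns=["event_type", "supercell_id",
                                         "supercell_area", "round_index",
                                         "span_lo", "span_hi"])
        return st.pair_events(df, "I-I")

    def test_offset_selection_isolates_consecutive_pairs(self):
        scatter = self._three_cluster_scatter()
        sel = st.select_cluster(scatter, strategy="offset", offset=1,
                                edge_margin_sds=0.0)
        assert (sel.selected.offset == 1).all()
        assert len(sel.selected) == 600

    def test_edge_margin_removes_span_edge_cluster(self):
        scatter = self._three_cluster_scatter()
        sel_all = st.select_cluster(scatter, offset=1, edge_margin_sds=0.0)
        sel_edge = st.select_cluster(scatter, offset=1, edge_margin_sds=1.0)
        assert len(sel_all.selected) == 600
        # the round 1 -> 2 cluster (y ~ 4, at the span edge) is dropped
        assert len(sel_edge.selected) == 300
        assert (sel_edge.selected.round_x == 0).all()

    def test_missing_offset_reports_counts(self):
        df = events_df([("initiation", 0, 1.0, 0), ("initiation", 0, 2.0, 2)])
        scatter = st.pair_events(df, "I-I")
        with pytest.raises(ValueError, match="offset"):
            st.select_cluster(scatter, offset=5)

    def test_density_strategy_keeps_dense_mode(self):
        scatter = self._three_cluster_scatter()
        sel = st.select_cluster(scatter, strategy="density",
                                density_frac=0.3)
        assert 0 < len(sel.selected) < len(scatter.data)


class TestBivariateGaussianFit:
    def test_uncorrelated_sample_rho_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 4000)
        y = rng.normal(0, 1, 4000)
        est = st.fit_bivariate_gaussian_bg(x, y)
        assert est.ci67[0] - 0.05 <= 0.0 <= est.ci67[1] + 0.05
        assert abs(est.rho) < 0.05

    def test_correlated_sample_with_background(self):
        """rho = 0.6 bivariate Gaussian plus 10% uniform background."""
        rng = np.random.default_rng(7)
        n = 5000
        cov = [[1.0, 0.6], [0.6, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=int(n * 0.9))
        bg = rng.uniform(-4, 4, size=(n - len(xy), 2))
        x, y = np.vstack([xy, bg]).T
        est = st.fit_bivariate_gaussian_bg(x, y)
        assert est.rho == pytest.approx(0.6, abs=0.05)
        assert est.background > 0

    def test_axis_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        cov = [[1.0, 0.45], [0.45, 1.0]]
        x, y = rng.multivariate_normal([2, 3], cov, size=3000).T
        a = st.fit_bivariate_gaussian_bg(x, y)
        b = st.fit_bivariate_gaussian_bg(x * 1000.0, y * 0.01)
        assert a.rho == pytest.approx(b.rho, abs=0.01)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            st.fit_bivariate_gaussian_bg(np.ones(50), np.ones(50))


class TestPartialCorrelation:
    def test_no_confounding_identity(self):
        assert st.partial_correlation(0.4, 0.0, 0.0) == pytest.approx(0.4)

    def test_exact_conditional_independence(self):
        assert st.partial_correlation(0.3, 0.6, 0.5) == pytest.approx(0.0)

    def test_formula_value(self):
        assert st.partial_correlation(0.5, 0.6, 0.5) == \
            pytest.approx(0.2887, abs=1e-4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.partial_correlation(0.5, 1.0, 0.3)

    @given(hst.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_matches_residual_regression_oracle(self, seed):
        """The partial-correlation formula equals the correlation of the
        residuals from regressing T and I2 on I1, on any trivariate sample."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3))
        cov = A @ A.T + 0.5 * np.eye(3)
        sample = rng.multivariate_normal(np.zeros(3), cov, size=400)
        t, i1, i2 = sample.T
        r = np.corrcoef(sample.T)
        formula = st.partial_correlation(r[0, 2], r[0, 1], r[1, 2])

        def resid(v, u):
            slope = np.cov(v, u)[0, 1] / np.var(u)
            return v - slope * u
        oracle = np.corrcoef(resid(t, i1), resid(i2, i1))[0, 1]
        assert formula == pytest.approx(oracle, abs=1e-3)


class TestDilutionAnalysis:
    @staticmethod
    def make_bins(a, pre_fold=2.0, noise=0.0, seed=0, tau=90.0, n_exp=3):
        rng = np.random.default_rng(seed)
        rows = []
        for exp in range(n_exp):
            for strain in ("test", "reference"):
                for b in range(11):
                    t = -90 + 30 * b + 15
                    fold = sim.dnaA_fold_change(t, 0.0, tau, pre_fold)
                    s = fold ** (-a) if strain == "test" else 1.0
                    s *= math.exp(noise * rng.standard_normal())
                    rows.append((exp, strain, b, t, s, tau, 20))
        return pd.DataFrame(rows, columns=[
            "experiment", "strain", "bin_index", "time_min",
            "mean_init_size", "mean_gen_time", "n_events"])

    def test_identical_series_fold_is_unity(self):
        bins = self.make_bins(a=0.0, pre_fold=1.0)
        fit = st.dilution_align_and_foldchange(bins)
        assert np.allclose(fit.table.fold_change, 1.0)
        assert all(b == 0 for b in fit.align_bins.values())

    def test_known_alignment_bin_recovered(self):
        # pre_fold 2 crosses the reference at one generation post swap
        bins = self.make_bins(a=0.3, pre_fold=2.0)
        fit = st.dilution_align_and_foldchange(bins)
        # crossing at t = 90 min lies between bins 5 and 6
        assert all(b in (5, 6) for b in fit.align_bins.values())

    def test_manual_override_reproduces_chosen_bin(self):
        bins = self.make_bins(a=0.3, noise=0.05, seed=3)
        fit = st.dilution_align_and_foldchange(bins, override_bin=3)
        assert all(b == 3 for b in fit.align_bins.values())
        t = fit.table
        for _, grp in t.groupby("experiment"):
            row = grp[grp.bin_index == 3]
            assert row.fold_change.iloc[0] == pytest.approx(1.0)
            assert row.norm_time.iloc[0] == pytest.approx(0.0)

    def test_noiseless_exponent_exact(self):
        for a in (0.0, 0.4, 1.0):
            bins = self.make_bins(a=a)
            fit = st.fit_dilution_exponent(
                st.dilution_align_and_foldchange(bins))
            assert fit.exponent_a == pytest.approx(a, abs=1e-6)


class TestPowerLaw:
    def test_constant_fold_zero_exponent(self):
        assert st.fit_power_law_exponent([1, 1, 1], [1, 0.5, 0.25]) == 0.0

    def test_inverse_concentration_unit_exponent(self):
        c = np.array([1.0, 0.5, 0.25, 0.125])
        assert st.fit_power_law_exponent(c ** -1.0, c) == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            st.fit_power_law_exponent([1.0, 2.0], [1.0, 0.5])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            st.fit_power_law_exponent([1.0, -2.0, 1.0], [1.0, 0.5, 0.2])
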