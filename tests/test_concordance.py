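"""Concordance inference: df rule, one-tailed tests, outliers, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as spstats

from emgvalence.concordance import (
    ConcordanceLMM,
    cross_correlation,
    df_m_l_1,
    group_summary,
    group_timecourse,
    one_tailed_p,
    sex_covariate_sensitivity,
    slope_t_test,
    zero_lag_correlation,
)
from emgvalence.config import SimulationConfig, TrialSpec
from emgvalence.simulate import simulate_paired_series

EXP1_TRIALS = [TrialSpec(60.0, "x", False, m) for m in (2.5, 3.5, 5.0, 6.5, 7.5)]


def _fit(df, direction="negative", **kw):
    return ConcordanceLMM.from_dataframe(df, **kw).fit(direction=direction)


class TestDfRule:
    @pytest.mark.parametrize("m,l,expected", [(15, 0, 14), (23, 0, 22), (10, 3, 6)])
    def test_values(self, m, l, expected):
        assert df_m_l_1(m, l) == expected

    @pytest.mark.parametrize("m,l", [(2, 1), (1, 0), (5, 4)])
    def test_too_few_participants_rejected(self, m, l):
        with pytest.raises(ValueError):
            df_m_l_1(m, l)


class TestOneTailedTest:
    def test_zero_slope_gives_half(self):
        assert one_tailed_p(0.0, 14, "negative") == pytest.approx(0.5)
        assert one_tailed_p(0.0, 14, "positive") == pytest.approx(0.5)

    def test_wrong_direction_exceeds_half(self):
        assert one_tailed_p(2.5, 14, "negative") > 0.5
        assert one_tailed_p(-2.5, 22, "positive") > 0.5

    def test_tail_probability_matches_incomplete_beta_oracle(self, rng):
        # independent closed form: P(T > t) = 0.5 * I_{df/(df+t^2)}(df/2, 1/2), t>0
        for _ in range(50):
            t = rng.normal(0, 3)
            df = int(rng.integers(3, 40))
            p_pos = one_tailed_p(t, df, "positive")
            x = df / (df + t * t)
            tail = 0.5 * special.betainc(df / 2.0, 0.5, x)
            expected = tail if t >= 0 else 1.0 - tail
            assert p_pos == pytest.approx(expected, abs=1e-12)

    def test_nonconverged_model_refused(self):
        cfg = SimulationConfig(n_participants=5, seed=1,
                               trial_spec=[TrialSpec(30.0, "x", False, 5.0)])
        df, _ = simulate_paired_series(cfg, "cs", seed=1)
        res = _fit(df)
        res.fit.converged = False
        with pytest.raises(RuntimeError, match="converge"):
            slope_t_test(res)


class TestOutlierMachinery:
    def test_noise_free_data_has_no_outliers(self):
        rng = np.random.default_rng(2)
        rows = []
        for j in range(5):
            x = rng.uniform(1, 9, 40)
            for xi in x:
                rows.append((f"P{j}", xi, -0.3 * xi + 1.0))
        df = pd.DataFrame(rows, columns=["participant", "valence", "emg_z"])
        res = _fit(df)
        assert not res.outlier_mask().any()
        assert res.outlier_fraction == 0.0

    def test_injected_gross_outlier_is_flagged_and_refit_improves(self):
        # bounded (uniform) noise cannot exceed ~1.8 SD, so the injected
        # +10 SD point is the only possible outlier
        rng = np.random.default_rng(3)
        truth_slope = -0.2
        rows = []
        for j in range(8):
            icept = 0.1 * rng.standard_normal()
            x = rng.uniform(1, 9, 50)
            y = icept + truth_slope * (x - 5.0) + rng.uniform(-0.8, 0.8, 50)
            rows += list(zip([f"P{j}"] * 50, x, y))
        df = pd.DataFrame(rows, columns=["participant", "valence", "emg_z"])
        res0 = _fit(df)
        sigma = np.sqrt(res0.sigma2)
        # place the +10 SD point at a high-leverage valence so its bias
        # direction is away from the generating slope
        lean = np.sign(res0.beta - truth_slope)
        centered = df.valence - df.groupby("participant").valence.transform("mean")
        idx = int((lean * centered).idxmax())
        df2 = df.copy()
        df2.loc[idx, "emg_z"] += 10.0 * sigma
        res = _fit(df2)
        mask = res.outlier_mask()
        assert mask[idx]
        assert mask.sum() == 1  # exactly the injected point
        refit = res.refit_without_outliers()
        assert abs(refit.beta - truth_slope) <= abs(res.beta - truth_slope) + 1e-9
        assert abs(refit.beta - res0.beta) < abs(res.beta - res0.beta)
        assert refit.llf >= res.llf  # gross injected point dominated the deviance
        assert refit.df == res.df  # m - l - 1 unchanged by observation removal
        assert 0.0 <= res.outlier_fraction <= 100.0

    def test_marginal_and_conditional_residuals_both_available(self):
        cfg = SimulationConfig(n_participants=5, seed=4,
                               trial_spec=[TrialSpec(40.0, "x", False, 5.0)])
        df, _ = simulate_paired_series(cfg, "zm", seed=4)
        res = _fit(df, direction="positive")
        rc = res.standardized_residuals("conditional")
        rm = res.standardized_residuals("marginal")
        assert rc.shape == rm.shape
        assert np.std(rc) <= np.std(rm) + 1e-9


class TestCrossCorrelation:
    def test_identity_and_negation(self, rng):
        x = rng.standard_normal(100)
        assert zero_lag_correlation(x, x) == pytest.approx(1.0)
        assert zero_lag_correlation(x, -x) == pytest.approx(-1.0)

    def test_shifted_series_peaks_at_shift(self, rng):
        x = np.cumsum(rng.standard_normal(300))  # smooth-ish
        y = np.empty_like(x)
        y[3:] = x[:-3]
        y[:3] = x[0]
        cc = cross_correlation(x, y, max_lag_s=10)
        best = cc.loc[cc.r.idxmax(), "lag_s"]
        assert best == 3

    def test_constant_series_reported_missing(self):
        assert np.isnan(zero_lag_correlation(np.ones(10), np.arange(10.0)))


class TestGroupSummary:
    def test_identical_participants_mean_equals_either(self, rng):
        x = rng.uniform(1, 9, 50)
        y = 0.4 * x + rng.standard_normal(50)
        df = pd.DataFrame(
            {
                "participant": ["P1"] * 50 + ["P2"] * 50,
                "valence": np.r_[x, x],
                "emg_z": np.r_[y, y],
            }
        )
        tab, _ = group_summary(df)
        one = pd.DataFrame({"valence": x.round(1), "emg_z": y}).groupby("valence").emg_z.mean()
        np.testing.assert_allclose(tab.set_index("valence").emg_mean, one.sort_index())

    def test_noiseless_linear_data_recovers_generating_line(self, rng):
        x = rng.uniform(1, 9, 200)
        df = pd.DataFrame(
            {"participant": "P1", "valence": x, "emg_z": -0.25 * x + 2.0}
        )
        tab, (b0, b1) = group_summary(df, decimals=6)
        assert b1 == pytest.approx(-0.25, abs=1e-6)
        assert b0 == pytest.approx(2.0, abs=1e-6)

    def test_line_matches_independent_least_squares(self, rng):
        x = rng.uniform(1, 9, 120)
        y = 0.2 * x + rng.standard_normal(120)
        df = pd.DataFrame({"participant": "P1", "valence": x, "emg_z": y})
        tab, (b0, b1) = group_summary(df)
        A = np.column_stack([np.ones(len(tab)), tab.valence])
        coef, *_ = np.linalg.lstsq(A, tab.emg_mean, rcond=None)
        assert b0 == pytest.approx(coef[0], abs=1e-9)
        assert b1 == pytest.approx(coef[1], abs=1e-9)

    def test_timecourse_end_point_covers_90pct_of_trials(self, rng):
        rows = []
        lengths = {"T01": 20, "T02": 35, "T03": 40, "T04": 45, "T05": 50,
                   "T06": 30, "T07": 33, "T08": 42, "T09": 44, "T10": 48}
        for tid, ln in lengths.items():
            for t in range(ln):
                rows.append(("P1", tid, t, rng.standard_normal()))
        df = pd.DataFrame(rows, columns=["participant", "trial_id", "t_bin_s", "emg_z"])
        tc = group_timecourse(df)
        expected = float(np.ceil(np.quantile(list(lengths.values()), 0.90)))
        assert tc.attrs["end_point_s"] == expected
        assert tc.t_bin_s.max() == expected - 1


class TestSexCovariate:
    @staticmethod
    def _data(seed, n=15):
        cfg = SimulationConfig(n_participants=n, seed=seed, tau_intercept=0.3,
                               trial_spec=[TrialSpec(50.0, "x", False, 5.0)])
        df, _ = simulate_paired_series(cfg, "cs", seed=seed)
        rng = np.random.default_rng(seed + 1)
        parts = sorted(df.participant.unique())
        sex = {p: ("f" if rng.random() < 0.5 else "m") for p in parts}
        if len(set(sex.values())) < 2:  # force both levels
            sex[parts[0]] = "f"
            sex[parts[1]] = "m"
        return df, sex

    def test_df_drops_by_one_with_level2_predictor(self):
        df, sex = self._data(5)
        rep = sex_covariate_sensitivity(df, sex, direction="negative")
        assert rep["df_adjusted"] == 13

    def test_independent_covariate_barely_moves_slope(self):
        df, sex = self._data(6)
        rep = sex_covariate_sensitivity(df, sex, direction="negative")
        res = _fit(df)
        assert abs(rep["beta_adjusted"] - rep["beta_original"]) < 2 * res.se

    def test_single_sex_sample_rejected(self):
        df, sex = self._data(7)
        with pytest.raises(ValueError, match="levels"):
            sex_covariate_sensitivity(df, {p: "f" for p in sex}, direction="negative")

    def test_null_covariate_p_values_uniform(self):
        # sex assigned independently of everything: its p-values should be
        # ~ U(0,1); KS test over 200 replicate simulations at alpha = 0.01
        pvals = []
        for rep in range(200):
            df, sex = self._data(1000 + rep, n=12)
            out = sex_covariate_sensitivity(df, sex, direction="negative")
            pvals.append(out["covariate_p"])
        stat = spstats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01


class TestModelContainer:
    def test_missing_pairs_dropped_pairwise(self):
        df = pd.DataFrame(
            {
                "participant": ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4,
                "valence": [1, 2, np.nan, 4] * 3,
                "emg_z": [0.1, np.nan, 0.3, 0.4] * 3,
            }
        )
        m = ConcordanceLMM.from_dataframe(df)
        assert len(m.endog) == 6

    def test_summary_contains_headline_numbers(self):
        cfg = SimulationConfig(n_participants=5, seed=8,
                               trial_spec=[TrialSpec(40.0, "x", False, 5.0)])
        df, _ = simulate_paired_series(cfg, "cs", seed=8)
        res = _fit(df, muscle="cs", device="wired")
        s = res.summary()
        assert "gamma10" in s and f"{res.beta:.4f}" in s and "14" not in s[:0]
        row = res.to_row()
        assert set(row) >= {"beta", "se", "t", "df", "p_one_tailed", "outlier_pct"}

    def test_plot_group_scatter_smoke(self):
        import matplotlib

        matplotlib.use("Agg")
        cfg = SimulationConfig(n_participants=4, seed=9,
                               trial_spec=[TrialSpec(30.0, "x", False, 5.0)])
        df, _ = simulate_paired_series(cfg, "zm", seed=9)
        res = _fit(df, direction="positive", muscle="zm")
        ax = res.plot_group_scatter()
        assert ax.get_xlabel() == "valence rating"
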