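import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tmecrosstalk.stats import (fdr_adjust, fisher_combined, fit_dose_response_lmm,
                                fit_hier_shift, lrt_activation, per_patient_activation,
                                screen_pathways)
from tmecrosstalk.synthetic import CohortConfig, generate_score_cohort

from conftest import dense_hier_loglik


def _tiny_dataset(seed=2, n_pat=3, n_cells=8, shift=0.5):
    rng = np.random.default_rng(seed)
    pat = np.repeat([f"p{i}" for i in range(n_pat)], n_cells)
    t = np.tile(np.repeat([0, 1], n_cells // 2), n_pat)
    y = rng.normal(0, 1, n_pat * n_cells) + shift * t
    return y, pat, t


class TestHierShift:
    def test_loglik_matches_dense_mvn_oracle(self):
        for seed in range(4):
            y, pat, t = _tiny_dataset(seed=seed, n_pat=3, n_cells=10 if seed % 2 else 8)
            fit = fit_hier_shift(y, pat, t, min_cells=2)
            oracle = dense_hier_loglik(y, pat, t, fit.beta0, fit.beta_t,
                                       fit.Omega_u, fit.sigma_e2)
            assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        import warnings

        import statsmodels.formula.api as smf

        y, pat, t = _tiny_dataset(seed=9, n_pat=4, n_cells=20)
        fit = fit_hier_shift(y, pat, t, min_cells=2)
        df = pd.DataFrame({"y": y, "pat": pat, "t": t.astype(float)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm("y ~ t", df, groups=df["pat"], re_formula="~t").fit(reml=False)
        assert fit.beta_t == pytest.approx(float(sm_fit.fe_params["t"]), abs=1e-4)
        # our direct ML optimum is never worse than the reference fit
        assert fit.loglik >= float(sm_fit.llf) - 1e-6

    def test_recovers_generator_truth_within_3se(self):
        cfg = CohortConfig(n_patients=20, n_cells_per_sample=200, beta_t_effect=0.01,
                           sigma_e=0.02, n_pathways=1, frac_active_pathways=1.0, seed=1)
        scores, meta, truth = generate_score_cohort(cfg)
        fit = fit_hier_shift(scores.iloc[:, 0].to_numpy(), meta["patient"], meta["t"])
        assert abs(fit.beta_t - 0.01) < 3 * fit.se_beta_t

    def test_constant_data_degenerate(self):
        pat = np.repeat(["a", "b"], 40)
        t = np.tile(np.repeat([0, 1], 20), 2)
        fit = fit_hier_shift(np.full(80, 3.7), pat, t)
        assert fit.degenerate
        assert fit.beta0 == pytest.approx(3.7)
        assert fit.beta_t == 0.0

    def test_invariant_to_cell_duplication(self):
        y, pat, t = _tiny_dataset(seed=5, n_pat=4, n_cells=40)
        f1 = fit_hier_shift(y, pat, t)
        f2 = fit_hier_shift(np.r_[y, y], np.r_[pat, pat], np.r_[t, t])
        assert f2.beta0 == pytest.approx(f1.beta0, abs=1e-8)
        assert f2.beta_t == pytest.approx(f1.beta_t, abs=1e-8)

    def test_missing_timepoint_rejected(self):
        y = np.ones(60)
        pat = np.repeat(["a", "b"], 30)
        t = np.r_[np.repeat([0, 1], 15), np.zeros(30, int)]  # patient b lacks t=1
        with pytest.raises(ValueError, match="missing a timepoint"):
            fit_hier_shift(y + np.arange(60) * 0.01, pat, t, min_cells=2)


class TestLrt:
    def test_lrt_zero_when_logliks_equal(self):
        y, pat, t = _tiny_dataset(shift=0.0)
        full = fit_hier_shift(y, pat, t, min_cells=2)
        null = fit_hier_shift(y, pat, t, null=True, min_cells=2)
        null_same = type(null)(**{**null.__dict__, "loglik": full.loglik})
        tr = lrt_activation(full, null_same)
        assert tr.statistic == 0.0 and tr.p_value == 1.0

    def test_optimization_failure_surfaced(self):
        y, pat, t = _tiny_dataset()
        full = fit_hier_shift(y, pat, t, min_cells=2)
        bad_null = type(full)(**{**full.__dict__, "loglik": full.loglik + 5.0,
                                 "null_model": True})
        with pytest.raises(RuntimeError, match="optimization failure"):
            lrt_activation(full, bad_null)

    def test_requires_null_fit(self):
        y, pat, t = _tiny_dataset()
        full = fit_hier_shift(y, pat, t, min_cells=2)
        with pytest.raises(ValueError, match="null"):
            lrt_activation(full, full)

    def test_invariant_to_constant_shift(self):
        y, pat, t = _tiny_dataset(seed=7, n_pat=4, n_cells=40)
        s1 = lrt_activation(fit_hier_shift(y, pat, t),
                            fit_hier_shift(y, pat, t, null=True)).statistic
        s2 = lrt_activation(fit_hier_shift(y + 100.0, pat, t),
                            fit_hier_shift(y + 100.0, pat, t, null=True)).statistic
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_power_at_large_effect(self):
        """beta_t = 2 sigma_e is detected nearly always at 20 patients x 200 cells."""
        hits = 0
        n_sims = 25
        for s in range(n_sims):
            cfg = CohortConfig(n_patients=20, n_cells_per_sample=200,
                               beta_t_effect=0.04, sigma_e=0.02, sigma_u0=0.02,
                               sigma_ut=0.01, n_pathways=1, frac_active_pathways=1.0,
                               seed=3000 + s)
            scores, meta, _ = generate_score_cohort(cfg)
            y = scores.iloc[:, 0].to_numpy()
            tr = lrt_activation(fit_hier_shift(y, meta["patient"], meta["t"], n_restarts=2),
                                fit_hier_shift(y, meta["patient"], meta["t"], null=True,
                                               n_restarts=2))
            hits += tr.p_value < 0.05
        assert hits / n_sims > 0.9


class TestFdr:
    def test_hand_computed_bh(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_excluded_from_m(self):
        q = fdr_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], fdr_adjust([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_and_dominates_bonferroni(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 40)))
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in sorted-p order
        assert np.all(q <= np.minimum(p * p.size, 1.0) + 1e-12)  # never above Bonferroni
        assert np.all(q >= p - 1e-12)


class TestPerPatient:
    def test_clear_separation(self):
        rng = np.random.default_rng(0)
        pre = rng.normal(0, 0.1, 50)
        post = pre + 1.0
        tr = per_patient_activation(np.r_[pre, post], np.r_[np.zeros(50), np.ones(50)])
        assert tr.p_value < 1e-10
        assert tr.estimate == pytest.approx(1.0, abs=0.05)

    def test_missing_timepoint(self):
        with pytest.raises(ValueError, match="missing timepoint"):
            per_patient_activation(np.ones(10), np.ones(10))

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(500):
            y = rng.normal(size=60)
            ps.append(per_patient_activation(y, np.r_[np.zeros(30), np.ones(30)]).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestFisher:
    def test_single_p(self):
        chi2, df, p = fisher_combined([0.05])
        assert chi2 == pytest.approx(-2 * np.log(0.05))
        assert df == 2

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            fisher_combined([0.5, 0.0])

    def test_combined_matches_chi2_tail(self):
        chi2, df, p = fisher_combined([0.1, 0.2, 0.3])
        assert p == pytest.approx(float(sps.chi2.sf(chi2, df)))


class TestScreen:
    def test_null_and_active_pathways_separated(self):
        cfg = CohortConfig(n_patients=12, n_cells_per_sample=100, beta_t_effect=0.06,
                           sigma_e=0.02, sigma_u0=0.01, sigma_ut=0.005,
                           n_pathways=6, frac_active_pathways=0.5, seed=21)
        scores, meta, truth = generate_score_cohort(cfg)
        res = screen_pathways(scores, meta["patient"], meta["t"], n_restarts=2)
        active = [pw for pw, b in truth.items() if b != 0]
        nulls = [pw for pw, b in truth.items() if b == 0]
        res = res.set_index("pathway")
        assert (res.loc[active, "q"] < 0.05).all()
        assert res.loc[nulls, "lrt_stat"].max() < res.loc[active, "lrt_stat"].min()


class TestDoseResponseLmm:
    @staticmethod
    def _simulate(beta_fulv=-0.5, beta_afat=0.3, seed=0, n_lin=4, n_rep=3):
        rng = np.random.default_rng(seed)
        rows = []
        for li in range(n_lin):
            u0, u1 = rng.normal(0, 0.3), rng.normal(0, 0.1)
            for rep in range(n_rep):
                v = rng.normal(0, 0.1)
                for fulv in (0.0, 1.0, 4.0, 9.0):
                    for afat in (0.0, 0.5):
                        y = (2.0 + u0 + v + (beta_fulv + u1) * np.sqrt(fulv)
                             + beta_afat * afat + rng.normal(0, 0.05))
                        rows.append((y, fulv, afat, f"lin{li}", f"lin{li}_r{rep}"))
        return pd.DataFrame(rows, columns=["y", "fulv", "afat", "lineage", "rep"])

    def test_recovers_fulvestrant_slope(self):
        df = self._simulate(seed=3)
        res = fit_dose_response_lmm(df["y"], df["fulv"], df["afat"], df["lineage"], df["rep"])
        assert abs(res["beta_fulv"] - (-0.5)) < 3 * res["se"]["sqrt_fulv"]
        assert res["tests"]["sqrt_fulv"].p_value < 0.05

    def test_all_zero_afatinib_dropped(self):
        df = self._simulate(seed=4)
        df["afat"] = 0.0
        res = fit_dose_response_lmm(df["y"], df["fulv"], df["afat"], df["lineage"], df["rep"])
        assert np.isnan(res["beta_afat"])
        assert "afatinib_unidentifiable" in res["flags"]

    def test_constant_responses_degenerate(self):
        df = self._simulate(seed=5)
        df["y"] = 1.0
        res = fit_dose_response_lmm(df["y"], df["fulv"], df["afat"], df["lineage"], df["rep"])
        assert res["flags"] == ["degenerate"]
        assert res["beta_fulv"] == 0.0

    def test_single_replicate_collapses_nesting(self):
        df = self._simulate(seed=6, n_rep=1)
        with pytest.warns(UserWarning, match="nested replicate"):
            res = fit_dose_response_lmm(df["y"], df["fulv"], df["afat"],
                                        df["lineage"], df["rep"])
        assert "replicate_nesting_collapsed" in res["flags"]
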