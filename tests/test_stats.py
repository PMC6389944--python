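"""GLM associations, Freedman–Lane max-|t| permutation correction,
binary contrast, LOO sensitivity, global PCA and score correlation —
with independent oracles (normal equations, statsmodels, brute-force
permutation enumeration)."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from cnvtract.simulate import SimulationDesign, build_cohort, \
    simulate_feature_table
from cnvtract.stats import (binary_model, cc_ratio_test, design_matrix,
                            fit_glm, global_pca_test, loo_cnv_sensitivity,
                            permutation_correct, score_correlation)
from tests.conftest import make_cohort


class TestFitGlm:
    def test_matches_normal_equations_and_statsmodels(self, small_cohort):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, len(small_cohort)) \
            + 0.02 * small_cohort["P_DD"].to_numpy()
        res = fit_glm(y, small_cohort, "P_DD", diffusion_derived=True)
        X, _ = design_matrix(small_cohort, "P_DD", diffusion_derived=True)
        # explicit normal-equations oracle
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        # statsmodels as an independent implementation
        fit = sm.OLS(y, X).fit()
        assert res.t == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_small_fixture_oracle(self):
        cohort = make_cohort(["22q11.2 deletion"] * 2 + ["3q29 deletion"] * 2,
                             n_controls=4, seed=2)
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 8)
        res = fit_glm(y, cohort, "P_Sz")
        X, _ = design_matrix(cohort, "P_Sz")
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.beta == pytest.approx(beta[1], abs=1e-10)

    def test_orthogonal_response_gives_zero_t(self, small_cohort):
        X, _ = design_matrix(small_cohort, "P_DD")
        Z = np.delete(X, 1, axis=1)
        pred_resid = X[:, 1] - Z @ np.linalg.lstsq(Z, X[:, 1], rcond=None)[0]
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, len(pred_resid))
        y = v - (v @ pred_resid) / (pred_resid @ pred_resid) * pred_resid
        res = fit_glm(y, small_cohort, "P_DD")
        assert abs(res.t) < 1e-8

    def test_perfect_fit_flagged_degenerate(self, small_cohort):
        y = small_cohort["P_DD"].to_numpy(dtype=float)
        res = fit_glm(y, small_cohort, "P_DD")
        assert res.degenerate and res.p > 0.0

    def test_collinear_design_names_columns(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["P_DD"] = cohort["age"]
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(np.ones(len(cohort)) + np.arange(len(cohort)),
                    cohort, "P_DD")

    def test_missing_values_dropped(self, small_cohort):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, len(small_cohort))
        y[:2] = np.nan
        res = fit_glm(y, small_cohort, "P_DD")
        assert res.n == len(small_cohort) - 2


def _manual_freedman_lane(Y, cohort, predictor, B, seed, diffusion=False):
    """Independent re-implementation of the max-|t| F-L correction."""
    X, _ = design_matrix(cohort, predictor, diffusion_derived=diffusion)
    n, p = X.shape
    Z = np.delete(X, 1, axis=1)
    G = Z @ np.linalg.pinv(Z)
    fitted = G @ Y
    E = Y - fitted

    def tvec(Ymat):
        XtXinv = np.linalg.inv(X.T @ X)
        beta = XtXinv @ X.T @ Ymat
        resid = Ymat - X @ beta
        rss = (resid ** 2).sum(axis=0)
        se = np.sqrt(rss / (n - p) * XtXinv[1, 1])
        return beta[1] / se

    t_obs = tvec(Y)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(Y.shape[1])
    for _ in range(B):
        perm = rng.permutation(n)
        t_b = tvec(fitted + E[perm])
        exceed += np.max(np.abs(t_b)) >= np.abs(t_obs) - 1e-12
    p_corr = (1 + exceed) / (B + 1)
    return t_obs, p_corr


class TestPermutationCorrect:
    def test_matches_independent_freedman_lane_bit_exact(self, small_cohort):
        Y = simulate_feature_table(small_cohort, 5, effect_slope=0.01,
                                   seed=21).to_numpy()
        res = permutation_correct(Y, small_cohort, "P_DD", B=300, seed=77)
        t_ref, p_ref = _manual_freedman_lane(Y, small_cohort, "P_DD",
                                             B=300, seed=77)
        for j, r in enumerate(res):
            assert r.t == pytest.approx(t_ref[j], abs=1e-10)
            assert r.p_corr == pytest.approx(max(p_ref[j], r.p), abs=1e-12)

    def test_single_feature_family_close_to_uncorrected_permutation_p(
            self, small_cohort):
        Y = simulate_feature_table(small_cohort, 1, effect_slope=0.008,
                                   seed=5).to_numpy()
        res = permutation_correct(Y, small_cohort, "P_DD", B=1000, seed=3)[0]
        _, p_ref = _manual_freedman_lane(Y, small_cohort, "P_DD",
                                         B=1000, seed=991)
        mc_se = np.sqrt(p_ref[0] * (1 - p_ref[0]) / 1000)
        assert abs(res.p_corr - p_ref[0]) <= 4 * mc_se + 2 / 1001

    def test_subset_monotonicity(self, small_cohort):
        Y = simulate_feature_table(small_cohort, 8, effect_slope=0.005,
                                   seed=13)
        full = permutation_correct(Y, small_cohort, "P_DD", B=500, seed=11)
        sub = permutation_correct(Y.iloc[:, :3], small_cohort, "P_DD",
                                  B=500, seed=11)
        for a, b in zip(full[:3], sub):
            assert a.p_corr >= b.p_corr - 1e-12

    def test_p_corr_bounded_by_p_and_one(self, small_cohort):
        Y = simulate_feature_table(small_cohort, 6, seed=17)
        for r in permutation_correct(Y, small_cohort, "P_DD", B=200, seed=1):
            assert 0.0 < r.p <= 1.0
            assert r.p <= r.p_corr <= 1.0

    def test_bit_exact_reproducibility(self, small_cohort):
        Y = simulate_feature_table(small_cohort, 4, seed=19)
        a = permutation_correct(Y, small_cohort, "P_DD", B=250, seed=42)
        b = permutation_correct(Y, small_cohort, "P_DD", B=250, seed=42)
        assert [r.p_corr for r in a] == [r.p_corr for r in b]

    def test_small_b_rejected(self, small_cohort):
        Y = simulate_feature_table(small_cohort, 2, seed=23)
        with pytest.raises(ValueError):
            permutation_correct(Y, small_cohort, "P_DD", B=50)

    def test_all_nan_family_rejected(self, small_cohort):
        Y = pd.DataFrame(np.nan, index=small_cohort.index, columns=["a"])
        with pytest.raises(ValueError, match="empty"):
            permutation_correct(Y, small_cohort, "P_DD", B=200)


class TestBinaryModel:
    def test_label_permuted_cohort_shows_no_effect(self):
        cohort = make_cohort(seed=31)
        rng = np.random.default_rng(31)
        Y = rng.normal(0, 1, (len(cohort), 10))
        res = binary_model(Y, cohort, B=300, seed=2)
        assert min(r.p_corr for r in res) > 0.05

    def test_response_equal_to_carrier_flag_degenerate(self, small_cohort):
        y = small_cohort["carrier"].to_numpy(dtype=float)
        res = binary_model(y.reshape(-1, 1), small_cohort)[0]
        assert res.degenerate

    def test_dose_response_favours_penetrance_model(self):
        # effect proportional to P: the continuous model should win on
        # |t| in most replicate cohorts
        wins = 0
        n_rep = 30
        for r in range(n_rep):
            cohort = build_cohort(SimulationDesign(seed=100 + r))
            Y = simulate_feature_table(cohort, 1, effect_slope=0.02,
                                       seed=200 + r)
            t_pen = fit_glm(Y.iloc[:, 0], cohort, "P_DD").t
            t_bin = fit_glm(Y.iloc[:, 0], cohort, "carrier").t
            wins += abs(t_pen) > abs(t_bin)
        assert wins / n_rep >= 0.8


class TestLooSensitivity:
    def test_effect_driven_by_one_cnv_shows_largest_delta(self):
        cohort = make_cohort(["22q11.2 deletion"] * 4 + ["15q11.2 BP1-2 deletion"] * 4,
                             n_controls=10, seed=41)
        rng = np.random.default_rng(141)
        y = rng.normal(0, 0.8, len(cohort))
        y[(cohort["cnv_label"] == "22q11.2 deletion").to_numpy()] += 1.0
        table = loo_cnv_sensitivity(y, cohort, "P_DD")
        assert table["delta_beta"].abs().idxmax() == "22q11.2 deletion"
        assert table["delta_t"].abs().idxmax() == "22q11.2 deletion"

    def test_omitting_absent_cnv_changes_nothing(self, small_cohort):
        rng = np.random.default_rng(43)
        y = rng.normal(0, 1, len(small_cohort))
        table = loo_cnv_sensitivity(y, small_cohort, "P_DD",
                                    labels=["NRXN1 deletion"])
        assert table.loc["NRXN1 deletion", "delta_t"] == pytest.approx(0.0)
        assert table.loc["NRXN1 deletion", "n_omitted"] == 0

    def test_carrier_bookkeeping_across_omission_rows(self, small_cohort):
        rng = np.random.default_rng(47)
        y = rng.normal(0, 1, len(small_cohort))
        table = loo_cnv_sensitivity(y, small_cohort, "P_DD")
        n_carriers = int(small_cohort["carrier"].sum())
        n_cnvs = small_cohort.loc[small_cohort.carrier == 1, "cnv_label"].nunique()
        carriers_used = sum(
            int(small_cohort[small_cohort["cnv_label"] != lab]["carrier"].sum())
            for lab in table.index)
        assert carriers_used == (n_cnvs - 1) * n_carriers

    def test_single_cnv_class_rejected(self):
        cohort = make_cohort(["3q29 deletion"] * 3, n_controls=6, seed=3)
        with pytest.raises(ValueError):
            loo_cnv_sensitivity(np.ones(9) + np.arange(9), cohort, "P_DD")


class TestGlobalPca:
    def test_rank_three_matrix_has_three_components(self, small_cohort):
        rng = np.random.default_rng(51)
        basis = rng.normal(0, 1, (3, 12))
        X = pd.DataFrame(rng.normal(0, 1, (len(small_cohort), 3)) @ basis,
                         index=small_cohort.index)
        res = global_pca_test(X, small_cohort, B=200, seed=1)
        assert np.all(res.explained_variance_ratio[:3] > 1e-6)
        assert res.explained_variance_ratio[3:].sum() < 1e-10

    def test_loadings_match_svd_oracle(self, small_cohort):
        rng = np.random.default_rng(53)
        X = pd.DataFrame(rng.normal(0, 1, (len(small_cohort), 4)),
                         index=small_cohort.index,
                         columns=list("abcd"))
        res = global_pca_test(X, small_cohort,
                              n_components_tested=2, B=200, seed=1)
        V = X.to_numpy()
        V = (V - V.mean(0)) / V.std(0, ddof=1)
        _, S, Vt = np.linalg.svd(V, full_matrices=False)
        for j in range(2):
            row = Vt[j]
            if row[np.argmax(np.abs(row))] < 0:
                row = -row
            assert np.allclose(res.loadings.iloc[j], row, atol=1e-8)

    def test_component_scores_are_orthogonal(self, small_cohort):
        rng = np.random.default_rng(59)
        X = pd.DataFrame(rng.normal(0, 1, (len(small_cohort), 10)),
                         index=small_cohort.index)
        res = global_pca_test(X, small_cohort, B=200, seed=1)
        C = np.corrcoef(res.scores.to_numpy(), rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-8

    def test_constant_column_dropped_with_warning(self, small_cohort):
        rng = np.random.default_rng(61)
        X = pd.DataFrame(rng.normal(0, 1, (len(small_cohort), 4)),
                         index=small_cohort.index, columns=list("abcd"))
        X["const"] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            res = global_pca_test(X, small_cohort, B=200, seed=1)
        assert "const" in res.dropped_columns

    def test_injected_latent_factor_recovered(self):
        # a factor proportional to P_DD loads on a third of the columns;
        # the matching component (and only it) should be flagged
        hits = 0
        n_rep = 15
        for r in range(n_rep):
            cohort = build_cohort(SimulationDesign(seed=300 + r))
            rng = np.random.default_rng(400 + r)
            n = len(cohort)
            X = rng.normal(0, 1, (n, 30))
            factor = 0.08 * cohort["P_DD"].to_numpy()
            X[:, :10] += factor[:, None] * rng.uniform(0.5, 1.5, 10)
            res = global_pca_test(pd.DataFrame(X, index=cohort.index),
                                  cohort, B=300, seed=500 + r,
                                  predictors=("P_DD",))
            sig = [x for x in res.results["P_DD"] if x.p_corr <= 0.05]
            if sig:
                scores = res.scores[[x.feature for x in sig]]
                cors = [abs(np.corrcoef(cohort["P_DD"], scores[c])[0, 1])
                        for c in scores.columns]
                hits += max(cors) > 0.5
        assert hits / n_rep >= 0.8


class TestCcRatio:
    def test_worked_ratio(self, small_cohort):
        body = np.full(len(small_cohort), 2000.0)
        spl = np.full(len(small_cohort), 4000.0)
        body = body + np.arange(len(body))  # avoid zero variance
        res = cc_ratio_test(body, spl, small_cohort)
        ratio = body / spl
        assert ratio[0] == pytest.approx(0.5)
        assert set(res) == {"P_Sz", "P_DD"}

    def test_null_ratio_t_centred_on_zero(self):
        ts = []
        for r in range(40):
            cohort = build_cohort(SimulationDesign(seed=600 + r))
            rng = np.random.default_rng(700 + r)
            body = 2000 + rng.normal(0, 100, len(cohort))
            spl = 4000 + rng.normal(0, 100, len(cohort))
            ts.append(cc_ratio_test(body, spl, cohort)["P_DD"].t)
        ts = np.array(ts)
        assert abs(ts.mean()) < 2.5 / np.sqrt(len(ts)) * 3

    def test_opposite_volume_slopes_recover_negative_association(self):
        hits = 0
        n_rep = 50
        for r in range(n_rep):
            cohort = build_cohort(SimulationDesign(seed=800 + r))
            rng = np.random.default_rng(900 + r)
            p = cohort["P_DD"].to_numpy()
            body = 2000 * (1 - 0.003 * p) + rng.normal(0, 100, len(cohort))
            spl = 4000 * (1 + 0.003 * p) + rng.normal(0, 150, len(cohort))
            res = cc_ratio_test(body, spl, cohort)["P_DD"]
            hits += (res.beta < 0) and (res.p < 0.05)
        assert hits / n_rep >= 0.8

    def test_zero_splenium_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            cc_ratio_test(np.ones(len(small_cohort)),
                          np.zeros(len(small_cohort)), small_cohort)


class TestScoreCorrelation:
    @staticmethod
    def _cohort_from_scores(psz, pdd):
        n = len(psz)
        return pd.DataFrame({
            "P_Sz": psz, "P_DD": pdd, "carrier": [1] * n,
            "cnv_label": ["22q11.2 deletion"] * n,
        }, index=[f"s{i}" for i in range(n)])

    def test_identical_ranking_gives_rho_one(self):
        c = self._cohort_from_scores([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert score_correlation(c).rho == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        c = self._cohort_from_scores([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert score_correlation(c).rho == pytest.approx(-1.0)

    def test_five_pair_fixture_matches_rank_then_pearson(self):
        psz = [2.0, 11.0, 4.7, 4.7, 0.5]
        pdd = [12.0, 88.0, 35.0, 31.0, 31.0]
        c = self._cohort_from_scores(psz, pdd)
        res = score_correlation(c)
        rx, ry = sps.rankdata(psz), sps.rankdata(pdd)
        rho_ref = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(rho_ref, abs=1e-12)
        # brute-force exact permutation p oracle
        ry0 = ry - ry.mean()
        rx0 = rx - rx.mean()
        denom = np.sqrt((rx0 @ rx0) * (ry0 @ ry0))
        rhos = [rx0 @ ry0[list(perm)] / denom
                for perm in itertools.permutations(range(5))]
        p_ref = np.mean(np.abs(rhos) >= abs(rho_ref) - 1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)
        assert res.method == "exact-permutation"

    def test_large_n_uses_t_approximation_matching_scipy(self):
        cohort = build_cohort(SimulationDesign(seed=12))
        res = score_correlation(cohort)
        ref = sps.spearmanr(cohort["P_Sz"], cohort["P_DD"])
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)
        assert res.method == "t-approximation"

    def test_carriers_subset_differs_from_all(self):
        cohort = build_cohort(SimulationDesign(seed=12))
        all_ = score_correlation(cohort, subset="all")
        carriers = score_correlation(cohort, subset="carriers")
        assert all_.n == 36 and carriers.n == 21
        assert 0 < carriers.rho < 1

    def test_zero_variance_flagged_undefined(self):
        c = self._cohort_from_scores([1.0] * 5, [1, 2, 3, 4, 5])
        res = score_correlation(c)
        assert not res.defined and np.isnan(res.rho)
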