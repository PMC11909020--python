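"""OLS engine, standardized-beta association, ΔadjR² and multiplicity."""

import numpy as np
import pandas as pd
import pytest

from prsdiff.config import RegressionSpec, SimulationConfig, ThresholdSet
from prsdiff.errors import RankDeficientError, ValidationError
from prsdiff.associate import (
    bonferroni_threshold,
    fit_ols,
    heatmap_table,
    prs_association,
    run_cortical_scan,
    threshold_profile,
)
from prsdiff.regions import DESIKAN_KILLIANY_REGIONS, cortical_outcomes
from prsdiff.simulate import simulate_phenotypes, simulate_truth, true_score


def normal_equations_oracle(y, X):
    """Textbook (XᵀX)⁻¹Xᵀy solution with classical SE/t/p formulas."""
    from scipy import stats as sps

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, k = X.shape
    df = n - k
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / tss
    adj = 1 - (1 - r2) * (n - 1) / df
    return beta, se, t, p, r2, adj


class TestFitOls:
    def test_perfect_linear_fit(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        X = np.column_stack([np.ones(10), x])
        fit = fit_ols(y, X, ["const", "x"])
        assert fit.params[1] == pytest.approx(2.0)
        assert fit.params[0] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0) and fit.adj_r2 == pytest.approx(1.0)

    def test_orthogonal_regressor_gets_zero_slope(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to x and constant
        X = np.column_stack([np.ones(4), x])
        fit = fit_ols(y, X)
        assert fit.params[1] == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 100))
        k = int(rng.integers(2, 6))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = X @ rng.normal(size=k) + rng.normal(size=n)
        fit = fit_ols(y, X)
        b, se, t, p, r2, adj = normal_equations_oracle(y, X)
        for got, want in ((fit.params, b), (fit.se, se), (fit.t, t),
                          (fit.p, p)):
            np.testing.assert_allclose(got, want, rtol=1e-8)
        assert fit.r2 == pytest.approx(r2, rel=1e-8)
        assert fit.adj_r2 == pytest.approx(adj, rel=1e-8)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(RankDeficientError) as err:
            fit_ols(rng.normal(size=30), X, ["const", "x", "x_copy"])
        assert err.value.columns  # at least one collinear column named

    def test_rejects_missing_values(self):
        X = np.ones((5, 1))
        y = np.array([1.0, 2, np.nan, 4, 5])
        with pytest.raises(ValidationError):
            fit_ols(y, X)


class TestBonferroni:
    def test_34_region_threshold_matches_printed_value(self):
        assert bonferroni_threshold(0.05, 34) == pytest.approx(1.47e-3,
                                                               rel=5e-3)

    def test_trivial_cases(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 4) == 0.0025

    def test_validation(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)


def _cov_frame(n, rng):
    return pd.DataFrame({
        "age": rng.uniform(18, 80, n),
        "sex": rng.integers(0, 2, n),
        "icv": rng.normal(1.5e6, 1.5e5, n),
    }, index=[f"s{i}" for i in range(n)])


class TestPrsAssociation:
    def test_self_regression_recovers_unity(self, rng):
        n = 200
        prs = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        cov = _cov_frame(n, rng)
        res = prs_association(prs.copy(), prs, cov,
                              RegressionSpec("cognition"), "self", 0.5)
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.delta_adj_r2 == pytest.approx(1.0, abs=0.02)

    def test_independent_prs_has_null_effect(self, rng):
        n = 10000
        idx = [f"s{i}" for i in range(n)]
        prs = pd.Series(rng.normal(size=n), index=idx)
        y = pd.Series(rng.normal(size=n), index=idx)
        res = prs_association(y, prs, _cov_frame(n, rng),
                              RegressionSpec("cognition"), "null", 0.5)
        assert abs(res.beta) < 0.03
        assert abs(res.delta_adj_r2) < 0.01

    def test_planted_effect_recovered_unbiasedly(self):
        # replicate-mean standardized beta ~ 0.21 at the study's n
        cfg = SimulationConfig(seed=42, n_target=168, n_blocks=4,
                               snps_per_block=25, prs_effect=0.21,
                               affected_regions=("WM",))
        from prsdiff.simulate import simulate_genotypes

        g, v = simulate_genotypes(cfg)
        truth = simulate_truth(v, cfg)
        s = pd.Series(true_score(g, truth), index=g.samples)
        rng = np.random.default_rng(99)
        betas = []
        for _ in range(150):
            ph, cov = simulate_phenotypes(g, truth, cfg, rng=rng)
            res = prs_association(ph.set_index("sample_id")["WM"], s,
                                  cov.set_index("sample_id"),
                                  RegressionSpec("cognition"), "WM", 0.5)
            betas.append(res.beta)
        assert np.mean(betas) == pytest.approx(0.21, abs=0.03)

    def test_listwise_subset_shared_by_both_models(self, rng):
        n = 120
        idx = [f"s{i}" for i in range(n)]
        prs = pd.Series(rng.normal(size=n), index=idx)
        y = pd.Series(rng.normal(size=n), index=idx)
        y.iloc[:30] = np.nan
        res = prs_association(y, prs, _cov_frame(n, rng),
                              RegressionSpec("cognition"), "y", 0.5)
        assert res.n == 90

    def test_outcome_rescaling_leaves_result_invariant(self, rng):
        n = 300
        idx = [f"s{i}" for i in range(n)]
        prs = pd.Series(rng.normal(size=n), index=idx)
        cov = _cov_frame(n, rng)
        y = pd.Series(0.3 * prs.to_numpy() + rng.normal(size=n), index=idx)
        a = prs_association(y, prs, cov, RegressionSpec("thickness"), "y", 0.5)
        b = prs_association(1000 + 50 * y, prs, cov,
                            RegressionSpec("thickness"), "y", 0.5)
        assert a.beta == pytest.approx(b.beta, rel=1e-10)
        assert a.p == pytest.approx(b.p, rel=1e-10)
        assert a.delta_adj_r2 == pytest.approx(b.delta_adj_r2, rel=1e-8)

    def test_delta_adj_r2_matches_partial_correlation(self, rng):
        n = 10000
        idx = [f"s{i}" for i in range(n)]
        prs_arr = rng.normal(size=n)
        cov = _cov_frame(n, rng)
        y_arr = 0.2 * (prs_arr - prs_arr.mean()) / prs_arr.std() \
            + rng.normal(size=n)
        res = prs_association(pd.Series(y_arr, index=idx),
                              pd.Series(prs_arr, index=idx), cov,
                              RegressionSpec("cognition"), "y", 0.5)
        # with orthogonal covariates ΔadjR² ≈ squared partial correlation
        r = np.corrcoef(prs_arr, y_arr)[0, 1]
        assert res.delta_adj_r2 == pytest.approx(r * r, abs=0.01)

    def test_subset_too_small_raises(self, rng):
        idx = [f"s{i}" for i in range(4)]
        prs = pd.Series(rng.normal(size=4), index=idx)
        y = pd.Series(rng.normal(size=4), index=idx)
        with pytest.raises(ValidationError):
            prs_association(y, prs, _cov_frame(4, rng),
                            RegressionSpec("cognition"), "y", 0.5)


def _scan_inputs(cfg, rng=None):
    from prsdiff.simulate import simulate_genotypes

    g, v = simulate_genotypes(cfg)
    truth = simulate_truth(v, cfg)
    ph, cov = simulate_phenotypes(g, truth, cfg, rng=rng)
    prs = pd.DataFrame({"sample_id": g.samples,
                        "z_0.5": true_score(g, truth)})
    return ph, prs, cov


class TestCorticalScan:
    def test_single_affected_region_uniquely_bonferroni_significant(self):
        cfg = SimulationConfig(seed=17, n_target=1000, n_blocks=4,
                               snps_per_block=25, prs_effect=0.4,
                               affected_regions=("lh_fusiform_area",))
        ph, prs, cov = _scan_inputs(cfg)
        res = run_cortical_scan(ph, prs, cov, ThresholdSet((0.5,)))
        sig = res[res["significant_bonferroni"]]
        assert list(sig["outcome"]) == ["lh_fusiform_area"]

    def test_null_scan_type_i_rate_within_binomial_bounds(self):
        cfg = SimulationConfig(seed=23, n_target=400, n_blocks=4,
                               snps_per_block=25, prs_effect=0.0)
        ph, prs, cov = _scan_inputs(cfg)
        res = run_cortical_scan(ph, prs, cov, ThresholdSet((0.5,)))
        n_tests = len(res)  # 34 x 2 x 2
        assert n_tests == 136
        hits = int(res["significant_nominal"].sum())
        # 99% binomial bounds around 5% of 136
        lo, hi = 0, 15
        assert lo <= hits <= hi

    def test_permuted_prs_destroys_association(self):
        cfg = SimulationConfig(seed=29, n_target=600, n_blocks=4,
                               snps_per_block=25, prs_effect=0.3,
                               affected_regions=("rh_insula_thickness",))
        ph, prs, cov = _scan_inputs(cfg)
        rng = np.random.default_rng(1)
        prs["z_0.5"] = rng.permutation(prs["z_0.5"].to_numpy())
        res = run_cortical_scan(ph, prs, cov, ThresholdSet((0.5,)))
        assert abs(res["beta"].mean()) < 0.02

    def test_bonferroni_implies_nominal_and_count_order(self, small_cohort):
        cfg, cohort = small_cohort
        prs = pd.DataFrame({"sample_id": cohort["genotypes"].samples,
                            "z_0.5": true_score(cohort["genotypes"],
                                                cohort["truth"])})
        res = run_cortical_scan(cohort["phenotypes"], prs,
                                cohort["covariates"], ThresholdSet((0.5,)))
        assert (res["significant_bonferroni"] <= res["significant_nominal"]).all()
        np.testing.assert_allclose(
            res["delta_adj_r2"], res["adj_r2_full"] - res["adj_r2_cov"],
            atol=1e-12)

    def test_missing_region_column_is_named(self, small_cohort):
        _, cohort = small_cohort
        prs = pd.DataFrame({"sample_id": cohort["genotypes"].samples,
                            "z_0.5": np.arange(cohort["genotypes"].n_samples,
                                               dtype=float)})
        ph = cohort["phenotypes"].drop(columns=["lh_cuneus_area"])
        with pytest.raises(ValidationError, match="lh_cuneus_area"):
            run_cortical_scan(ph, prs, cohort["covariates"],
                              ThresholdSet((0.5,)))

    def test_wide_views_cover_grid(self, small_cohort):
        _, cohort = small_cohort
        prs = pd.DataFrame({"sample_id": cohort["genotypes"].samples,
                            "z_0.5": true_score(cohort["genotypes"],
                                                cohort["truth"])})
        res = run_cortical_scan(cohort["phenotypes"], prs,
                                cohort["covariates"], ThresholdSet((0.5,)))
        heat = heatmap_table(res, 0.5)
        assert heat.shape == (34, 4)
        assert set(heat.index) == set(DESIKAN_KILLIANY_REGIONS)
        prof = threshold_profile(res, cortical_outcomes("area")[:3])
        assert prof.shape == (3, 1)
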