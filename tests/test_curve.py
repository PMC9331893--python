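"""Specification enumeration, standardized OLS fitting, curve summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import specurve as sc
from specurve.curve import (
    Specification,
    SpecResult,
    results_to_frame,
    sort_results,
)
from specurve.simulate import CONTENT_COLUMNS, COVARIATE_COLUMNS, OUTCOME_COLUMNS


def _zframe(rng, n, k_cov=2):
    cols = {"y": rng.normal(size=n), "x": rng.normal(size=n)}
    for i in range(k_cov):
        cols[f"c{i}"] = rng.normal(size=n)
    df = pd.DataFrame(cols)
    return (df - df.mean()) / df.std(ddof=1)


def _normal_equations_oracle(y, x_mat):
    """Independent OLS: explicit inverse of the normal equations."""
    xtx_inv = np.linalg.inv(x_mat.T @ x_mat)
    coef = xtx_inv @ x_mat.T @ y
    resid = y - x_mat @ coef
    df = len(y) - x_mat.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = coef / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return coef, se, t, p, df


class TestDesign:
    def test_default_lattice_has_seven_sets(self):
        sets = sc.build_covariate_sets(COVARIATE_COLUMNS)
        assert len(sets) == 7
        assert () in sets and tuple(COVARIATE_COLUMNS) in sets

    def test_lattice_degenerates(self):
        assert sc.build_covariate_sets([]) == [()]
        assert sc.build_covariate_sets(["c"]) == [(), ("c",)]

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            sc.build_covariate_sets(["a", "a"])

    def test_full_design_counts(self):
        sets = sc.build_covariate_sets(COVARIATE_COLUMNS)
        specs = sc.enumerate_specifications(CONTENT_COLUMNS, OUTCOME_COLUMNS, sets)
        assert len(specs) == 420
        per_pred = [s for s in specs if s.predictor == "content_01"]
        assert len(per_pred) == 21

    def test_order_is_outcome_major_and_matches_nested_loops(self):
        preds, outs, sets = ["x1", "x2"], ["y1", "y2"], [(), ("c",), ("d",)]
        specs = sc.enumerate_specifications(preds, outs, sets)
        expected = [
            Specification(o, x, tuple(c)) for o in outs for x in preds for c in sets
        ]
        assert specs == expected
        assert len(specs) == 12

    def test_singleton_product(self):
        assert len(sc.enumerate_specifications(["x"], ["y"], [()])) == 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            sc.enumerate_specifications([], ["y"], [()])

    def test_predictor_cannot_be_covariate(self):
        with pytest.raises(ValueError):
            Specification("y", "x", ("x",))
        with pytest.raises(ValueError):
            Specification("y", "x", ("y",))


class TestFitSpecification:
    def test_perfect_fit(self, rng):
        df = _zframe(rng, 30, k_cov=0)
        df["y"] = df["x"]
        res = sc.fit_specification(df, Specification("y", "x"))
        assert res.beta == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == 0.0
        assert res.partial_r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        df = _zframe(rng, 8, k_cov=1)
        df["y"] = (0.5 * df["x"] - 0.3 * df["c0"] + rng.normal(size=8)).pipe(
            lambda s: (s - s.mean()) / s.std(ddof=1)
        )
        res = sc.fit_specification(df, Specification("y", "x", ("c0",)))
        x_mat = np.column_stack([np.ones(8), df["x"], df["c0"]])
        coef, se, t, p, dof = _normal_equations_oracle(df["y"].to_numpy(), x_mat)
        assert res.beta == pytest.approx(coef[1], abs=1e-10)
        assert res.se == pytest.approx(se[1], abs=1e-10)
        assert res.t == pytest.approx(t[1], abs=1e-10)
        assert res.p_value == pytest.approx(p[1], abs=1e-10)
        assert res.df == dof

    def test_matches_statsmodels(self, rng):
        smf = pytest.importorskip("statsmodels.api")
        df = _zframe(rng, 40, k_cov=2)
        res = sc.fit_specification(df, Specification("y", "x", ("c0", "c1")))
        x_mat = smf.add_constant(df[["x", "c0", "c1"]])
        fit = smf.OLS(df["y"], x_mat).fit()
        assert res.beta == pytest.approx(fit.params["x"], abs=1e-10)
        assert res.se == pytest.approx(fit.bse["x"], abs=1e-10)
        assert res.p_value == pytest.approx(fit.pvalues["x"], abs=1e-10)
        ci = fit.conf_int().loc["x"]
        assert res.ci_low == pytest.approx(ci[0], abs=1e-10)
        assert res.ci_high == pytest.approx(ci[1], abs=1e-10)

    def test_zero_t_gives_zero_partial_r2(self):
        # y exactly orthogonal to x (and to the intercept)
        df = pd.DataFrame(
            {"y": [1.0, 1.0, -1.0, -1.0], "x": [1.0, -1.0, 1.0, -1.0]}
        )
        res = sc.fit_specification(df, Specification("y", "x"))
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.partial_r2 == pytest.approx(0.0, abs=1e-12)

    def test_no_covariates_beta_equals_pearson_r(self, rng):
        df = _zframe(rng, 200, k_cov=0)
        df["y"] = (df["x"] * 0.4 + rng.normal(size=200)).pipe(
            lambda s: (s - s.mean()) / s.std(ddof=1)
        )
        res = sc.fit_specification(df, Specification("y", "x"))
        assert res.beta == pytest.approx(np.corrcoef(df["y"], df["x"])[0, 1], abs=1e-10)

    def test_collinear_and_constant_regressors_rejected(self, rng):
        df = _zframe(rng, 20, k_cov=1)
        df["c1"] = df["x"]
        with pytest.raises(ValueError, match="collinear"):
            sc.fit_specification(df, Specification("y", "x", ("c0", "c1")))
        df["c2"] = 1.0
        with pytest.raises(ValueError, match="c2"):
            sc.fit_specification(df, Specification("y", "x", ("c2",)))

    def test_insufficient_rows_rejected(self, rng):
        df = _zframe(rng, 3, k_cov=1)
        with pytest.raises(ValueError, match="insufficient"):
            sc.fit_specification(df, Specification("y", "x", ("c0",)))

    def test_uncorrelated_covariate_barely_moves_beta(self, rng):
        df = _zframe(rng, 2000, k_cov=1)
        df["y"] = (0.3 * df["x"] + rng.normal(size=2000)).pipe(
            lambda s: (s - s.mean()) / s.std(ddof=1)
        )
        plain = sc.fit_specification(df, Specification("y", "x"))
        adjusted = sc.fit_specification(df, Specification("y", "x", ("c0",)))
        assert abs(adjusted.beta - plain.beta) < 2 * plain.se


class TestRunCurve:
    def test_one_result_per_spec_and_sorting(self, null_survey):
        sets = sc.build_covariate_sets(COVARIATE_COLUMNS)
        specs = sc.enumerate_specifications(CONTENT_COLUMNS[:3], OUTCOME_COLUMNS, sets)
        results = sc.run_curve(null_survey, specs)
        assert len(results) == len(specs) == 63
        betas = [r.beta for r in sort_results(results)]
        assert betas == sorted(betas)

    def test_single_spec(self, null_survey):
        specs = [Specification("peer", "content_02")]
        results = sc.run_curve(null_survey, specs)
        assert len(results) == 1
        assert sort_results(results) == results

    def test_null_significant_fraction(self):
        """Under the all-null generator about 5% of specifications are
        individually significant at alpha = 0.05.  The 420 p-values of one
        dataset cluster into ~60 effective tests, so the fraction is
        averaged over replicate datasets before asserting the band."""
        from conftest import prepare

        fracs = []
        for rep in range(10):
            cfg = sc.build_default_config(n_participants=1000)
            data = prepare(sc.generate_survey(cfg, seed=600 + rep))
            curve = sc.SpecificationCurve().fit(data)
            assert len(curve.results_) == 420
            fracs.append(np.mean([r.p_value < 0.05 for r in curve.results_]))
        assert 0.02 <= np.mean(fracs) <= 0.09

    def test_failing_spec_is_identified(self, null_survey):
        df = null_survey.copy()
        df["content_01"] = df["content_02"]
        specs = [Specification("peer", "content_01", ("content_02",))]
        with pytest.raises(ValueError, match="peer~content_01"):
            sc.run_curve(df, specs)


def _mk_result(beta, p, predictor="x", partial_r2=0.0):
    return SpecResult(
        spec=Specification("y", predictor),
        n=100,
        beta=beta,
        se=0.1,
        t=beta / 0.1,
        df=98,
        p_value=p,
        ci_low=beta - 0.2,
        ci_high=beta + 0.2,
        partial_r2=partial_r2,
    )


class TestSummarizeCurve:
    def test_hand_tally(self):
        betas = [-0.2, 0.1, 0.15, 0.02, 0.3]
        pvals = [0.001, 0.2, 0.03, 0.6, 0.04]
        results = [_mk_result(b, p) for b, p in zip(betas, pvals)]
        summ = sc.summarize_curve(results, alpha=0.05)
        assert summ.median_beta == pytest.approx(0.1)
        assert (summ.n_sig_pos, summ.n_sig_neg, summ.n_nonsig) == (2, 1, 2)
        assert summ.dominant_sign == "+"
        assert summ.nsrpd == 2

    def test_saturated_direction(self):
        results = [_mk_result(0.2, 0.001) for _ in range(21)]
        summ = sc.summarize_curve(results, alpha=0.05)
        assert summ.nsrpd == 21
        assert summ.n_nonsig == 0

    def test_even_count_median_is_mean_of_middle_two(self):
        results = [_mk_result(b, 0.5) for b in [0.1, 0.2, 0.4, 0.9]]
        assert sc.summarize_curve(results).median_beta == pytest.approx(0.3)

    def test_zero_median_tie_goes_to_larger_significant_count(self):
        results = [
            _mk_result(-0.2, 0.01),
            _mk_result(0.0, 0.9),
            _mk_result(0.2, 0.9),
        ]
        summ = sc.summarize_curve(results)
        assert summ.dominant_sign == "-"
        assert summ.nsrpd == 1

    def test_count_conservation_and_identity(self, null_survey):
        sets = sc.build_covariate_sets(COVARIATE_COLUMNS)
        specs = sc.enumerate_specifications(["content_05"], OUTCOME_COLUMNS, sets)
        results = sc.run_curve(null_survey, specs)
        summ = sc.summarize_curve(results)
        assert summ.n_specs == 21
        assert summ.n_sig_pos + summ.n_sig_neg + summ.n_nonsig == summ.n_specs
        for r in results:
            assert r.partial_r2 == pytest.approx(r.t**2 / (r.t**2 + r.df), abs=1e-12)

    def test_mixed_predictors_rejected(self):
        results = [_mk_result(0.1, 0.5, "x"), _mk_result(0.1, 0.5, "z")]
        with pytest.raises(ValueError, match="mixed"):
            sc.summarize_curve(results)
        with pytest.raises(ValueError):
            sc.summarize_curve([])


class TestEstimator:
    def test_fitted_attributes_and_frames(self, null_survey):
        est = sc.SpecificationCurve(predictors=CONTENT_COLUMNS[:2]).fit(null_survey)
        assert len(est.specs_) == 2 * 3 * 7
        assert set(est.summaries_) == {"content_01", "content_02"}
        frame = est.results_frame()
        assert len(frame) == 42
        curve = est.curve_frame()
        assert list(curve["x_index"]) == list(range(1, 43))
        assert curve["beta"].is_monotonic_increasing

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        est = sc.SpecificationCurve(alpha=0.01, predictors=["content_01"])
        cloned = clone(est)
        assert cloned.get_params()["alpha"] == 0.01
        cloned.set_params(alpha=0.10)
        assert cloned.alpha == 0.10

    def test_results_frame_covariates_joined(self, null_survey):
        est = sc.SpecificationCurve(predictors=["content_01"]).fit(null_survey)
        frame = results_to_frame(est.results_)
        joined = set(frame["covariates"])
        assert "" in joined and "+".join(COVARIATE_COLUMNS) in joined
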