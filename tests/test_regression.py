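"""Exact OLS from summaries: oracle agreement, guards, equivariance."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pcssreg import (
    GeneratorConfig,
    InsufficientSampleSize,
    InsufficientSampleSizeError,
    ModelSpec,
    PcssError,
    SingularDesignError,
    SummarySet,
    ZeroVariancePredictorError,
    add_group_indicators,
    fit_ols,
    fit_ols_ipd,
    fit_per_cohort,
    fit_stratified,
    generate_cohorts,
    max_relative_difference,
    summarize_ipd,
    summarize_ipd_stratified,
)
from conftest import summarize_df


@pytest.fixture(scope="module")
def toy8():
    r = np.random.default_rng(42)
    return pd.DataFrame(
        {
            "x1": r.normal(size=8),
            "x2": r.normal(size=8),
            "y": r.normal(size=8),
        }
    )


class TestFitOls:
    def test_orthogonal_predictor_slope_zero(self):
        s = SummarySet(
            ["y", "x"], [3.0, 1.0], [[2.0, 0.0], [0.0, 1.0]], 20
        )
        fit = fit_ols(s, ModelSpec("y", ["x"]))
        assert fit.estimate("x") == pytest.approx(0.0, abs=1e-14)
        assert fit.estimate("(Intercept)") == pytest.approx(3.0)

    def test_matches_statsmodels_on_toy_table(self, toy8):
        """Summary-only fit reproduces the row-level OLS (statsmodels)
        estimates, SEs, RSS, t and p on an 8-row table to 1e-10."""
        fit = fit_ols(summarize_df(toy8), ModelSpec("y", ["x1", "x2"]))
        X = sm.add_constant(toy8[["x1", "x2"]].to_numpy())
        ref = sm.OLS(toy8.y.to_numpy(), X).fit()
        np.testing.assert_allclose(fit.estimates, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.std_errors, ref.bse, rtol=1e-10)
        assert fit.rss == pytest.approx(float(ref.ssr), rel=1e-10)
        np.testing.assert_allclose(fit.t_stats, ref.tvalues, rtol=1e-10)
        np.testing.assert_allclose(fit.p_values, ref.pvalues, rtol=1e-10)
        ci = ref.conf_int()
        np.testing.assert_allclose(fit.ci_low, ci[:, 0], rtol=1e-9)
        np.testing.assert_allclose(fit.ci_high, ci[:, 1], rtol=1e-9)
        assert fit.df_resid == int(ref.df_resid)

    def test_pooled_pcss_equals_ipd_on_default_cohorts(self):
        tables = generate_cohorts(GeneratorConfig(seed=3))
        sets = summarize_ipd(tables)
        pooled = add_group_indicators(sets)
        fam = pooled.indicator_families["cohort"]
        spec = ModelSpec("trails_b", ["dha", "age", "sex", "bmi", *fam])
        fit = fit_ols(pooled, spec)
        ipd = fit_ols_ipd(tables, ModelSpec("trails_b", ["dha", "age", "sex", "bmi"]))
        assert max_relative_difference(fit, ipd) < 1e-8

    def test_scale_equivariance(self, toy8):
        s = summarize_df(toy8)
        base = fit_ols(s, ModelSpec("y", ["x1", "x2"]))
        c = 4.0
        scaled = s.copy()
        i = scaled.index("x1")
        scaled.means[i] *= c
        scaled.cov[i, :] *= c
        scaled.cov[:, i] *= c
        fit = fit_ols(scaled, ModelSpec("y", ["x1", "x2"]))
        assert fit.estimate("x1") == pytest.approx(base.estimate("x1") / c, rel=1e-12)
        assert fit.se("x1") == pytest.approx(base.se("x1") / c, rel=1e-12)
        assert fit.estimate("x2") == pytest.approx(base.estimate("x2"), rel=1e-12)

    def test_dropped_indicator_family_leaves_single_cohort_fit_unchanged(self, toy8):
        plain = fit_ols(summarize_df(toy8), ModelSpec("y", ["x1", "x2"]))
        pooled = add_group_indicators([summarize_df(toy8, "only")])
        fam = pooled.indicator_families["cohort"]
        with_fam = fit_ols(pooled, ModelSpec("y", ["x1", "x2", *fam]))
        assert with_fam.terms == plain.terms
        np.testing.assert_allclose(with_fam.estimates, plain.estimates, rtol=1e-12)
        np.testing.assert_allclose(with_fam.std_errors, plain.std_errors, rtol=1e-12)

    def test_guards(self, toy8):
        s = summarize_df(toy8)
        with pytest.raises(InsufficientSampleSizeError, match="insufficient sample size"):
            small = summarize_df(toy8.head(3))
            fit_ols(small, ModelSpec("y", ["x1", "x2"]))
        const = summarize_df(toy8.assign(flat=1.0))
        with pytest.raises(ZeroVariancePredictorError, match="'flat'"):
            fit_ols(const, ModelSpec("y", ["x1", "flat"]))
        dup = summarize_df(toy8.assign(x1b=toy8.x1))
        with pytest.raises(SingularDesignError, match="singular"):
            fit_ols(dup, ModelSpec("y", ["x1", "x1b", "x2"]))

    def test_predict_at_covariate_vector(self, toy8):
        fit = fit_ols(summarize_df(toy8), ModelSpec("y", ["x1", "x2"]))
        yhat = fit.predict({"x1": 1.0, "x2": -2.0})
        want = fit.estimate("(Intercept)") + fit.estimate("x1") - 2 * fit.estimate("x2")
        assert yhat == pytest.approx(want)


class TestFitStratified:
    def test_matches_stratum_ipd_and_orders_slopes(self):
        """With a negative carrier-specific slope addition, the carrier
        stratum's DHA slope is the steeper, and each stratified summary
        fit equals the corresponding row-level fit."""
        tables = generate_cohorts(GeneratorConfig(seed=11))
        cells = summarize_ipd_stratified(tables, "carrier")
        spec = ModelSpec("trails_b", ["dha", "age"])
        fits = fit_stratified(cells, spec)
        assert fits[1].estimate("dha") < fits[0].estimate("dha")
        for g in (0, 1):
            ipd = fit_ols_ipd(tables, spec, where=("carrier", g))
            assert max_relative_difference(fits[g], ipd) < 1e-8

    def test_slope_gap_shrinks_with_n_under_no_interaction(self):
        gaps = []
        for n in (500, 5000):
            cfg = GeneratorConfig(
                cohort_sizes=(n, n, n, n), b_int=0.0, seed=77
            )
            cells = summarize_ipd_stratified(generate_cohorts(cfg), "carrier")
            fits = fit_stratified(cells, ModelSpec("trails_b", ["dha", "age"]))
            gaps.append(abs(fits[1].estimate("dha") - fits[0].estimate("dha")))
        assert gaps[1] < gaps[0]

    def test_per_cohort_undersized_cell_yields_marker(self, rng):
        """A 6-row cell asked to support a 13-predictor model is flagged
        'insufficient sample size' instead of producing numbers."""
        names = [f"x{i}" for i in range(13)] + ["y"]
        cov = np.eye(14)
        cell = SummarySet(names, np.zeros(14), cov, 6, cohort_label="tiny")
        big = SummarySet(names, np.zeros(14), cov, 200, cohort_label="big")
        out = fit_per_cohort([cell, big], ModelSpec("y", names[:13]))
        assert isinstance(out["tiny"], InsufficientSampleSize)
        assert out["tiny"].n == 6
        assert "Insufficient Sample Size (n = 6)" in str(out["tiny"])
        assert not isinstance(out["big"], InsufficientSampleSize)


def test_reference_drop_override(toy8):
    df = toy8.assign(g1=[1, 1, 1, 1, 0, 0, 0, 0.0], g2=[0, 0, 0, 0, 1, 1, 1, 1.0])
    s = summarize_df(df)
    fit = fit_ols(s, ModelSpec("y", ["x1", "g1", "g2"], reference_drop=["g2"]))
    assert "g2" not in fit.terms and "g1" in fit.terms
    with pytest.raises(PcssError, match="unknown predictor"):
        fit_ols(s, ModelSpec("y", ["x1"], reference_drop=["g9"]))
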