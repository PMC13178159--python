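"""Exact pooling: sums-of-squares combination, indicators, stratified designs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pcssreg import (
    DuplicateLabelError,
    InsufficientCellError,
    PcssError,
    SummarySet,
    VariableMismatchError,
    add_group_indicators,
    build_stratified_design,
    pool_summaries,
)
from conftest import summarize_df

# Published per-cohort age descriptives: mean (SD) with cohort sizes.
AGE_ROWS = [(61.5, 4.8, 1201), (55.0, 4.1, 778), (58.8, 5.4, 135), (57.4, 5.5, 44)]


def age_sets():
    return [
        SummarySet(["age"], [m], [[sd**2]], n, cohort_label=f"c{i}")
        for i, (m, sd, n) in enumerate(AGE_ROWS)
    ]


def random_df(rng, n, cols=("x", "y")):
    return pd.DataFrame(rng.normal(size=(n, len(cols))), columns=list(cols))


class TestPoolSummaries:
    def test_reproduces_published_pooled_age(self):
        """Four cohort-level age summaries pool to 58.9 (5.5), the printed
        all-cohorts value, at printed (one-decimal) precision."""
        pooled = pool_summaries(age_sets()).summary
        assert pooled.n == 2158
        assert round(pooled.mean_of("age"), 1) == 58.9
        assert round(float(np.sqrt(pooled.var_of("age"))), 1) == 5.5

    def test_single_set_passes_through(self, toy_sets):
        pooled = pool_summaries([toy_sets[0]])
        np.testing.assert_array_equal(pooled.means, toy_sets[0].means)
        np.testing.assert_array_equal(pooled.cov, toy_sets[0].cov)
        assert pooled.n == toy_sets[0].n

    def test_equals_concatenation_oracle(self, toy_cohorts, toy_sets):
        concat = summarize_df(pd.concat(toy_cohorts.values(), ignore_index=True))
        pooled = pool_summaries(toy_sets).summary
        np.testing.assert_allclose(pooled.means, concat.means, rtol=1e-12)
        np.testing.assert_allclose(pooled.cov, concat.cov, rtol=1e-12)
        assert pooled.n == concat.n == 7

    def test_mismatched_variables_and_duplicate_labels(self, toy_sets):
        other = SummarySet(["x", "z"], [0, 0], np.eye(2), 5, "C")
        with pytest.raises(VariableMismatchError, match="'z'"):
            pool_summaries([toy_sets[0], other])
        with pytest.raises(DuplicateLabelError):
            pool_summaries([toy_sets[0], toy_sets[0]])


class TestGroupIndicators:
    def test_balanced_equal_means_give_zero_covariance(self, rng):
        df = random_df(rng, 8)
        a = summarize_df(df, "A")
        b = summarize_df(df, "B")  # identical cell, so means equal
        pooled = add_group_indicators([a, b])
        s = pooled.summary
        for ind in pooled.indicator_families["cohort"]:
            assert s.cov_of(ind, "x") == pytest.approx(0.0, abs=1e-12)
            assert s.cov_of(ind, "y") == pytest.approx(0.0, abs=1e-12)

    def test_indicator_means_are_proportions(self, rng):
        sets = [
            summarize_df(random_df(rng, n), lab)
            for lab, n in [("a", 2), ("b", 3), ("c", 5)]
        ]
        pooled = add_group_indicators(sets)
        means = [
            pooled.summary.mean_of(ind)
            for ind in pooled.indicator_families["cohort"]
        ]
        assert means == pytest.approx([0.2, 0.3, 0.5])
        assert sum(means) == pytest.approx(1.0)

    def test_matches_explicit_dummy_columns(self, rng, toy_cohorts):
        """Indicator moments equal those of explicit 0/1 columns on the
        concatenated table, and the closed-form identities hold."""
        labs = list(toy_cohorts)
        sets = [summarize_df(toy_cohorts[l], l) for l in labs]
        pooled = add_group_indicators(sets)
        frames = [
            toy_cohorts[l].assign(
                **{f"cohort[{m}]": float(m == l) for m in labs}
            )
            for l in labs
        ]
        oracle = summarize_df(pd.concat(frames, ignore_index=True))
        got = pooled.summary.subset(oracle.variables)
        np.testing.assert_allclose(got.means, oracle.means, rtol=1e-12)
        np.testing.assert_allclose(got.cov, oracle.cov, rtol=1e-12, atol=1e-14)
        # closed forms: cov(C_j, X) = n_j (xbar_j - xbar) / (N-1), etc.
        N = pooled.n
        s = pooled.summary
        grand_x = s.mean_of("x")
        for st_, lab in zip(sets, labs):
            ind = f"cohort[{lab}]"
            pj = st_.n / N
            assert s.cov_of(ind, "x") == pytest.approx(
                st_.n * (st_.mean_of("x") - grand_x) / (N - 1)
            )
            assert s.var_of(ind) == pytest.approx(N * pj * (1 - pj) / (N - 1))
        i0, i1 = (f"cohort[{l}]" for l in labs)
        p0, p1 = sets[0].n / N, sets[1].n / N
        assert s.cov_of(i0, i1) == pytest.approx(-N * p0 * p1 / (N - 1))


class TestStratifiedDesign:
    @staticmethod
    def cells_and_frames(rng, sizes=((4, 3), (3, 2))):
        strata = {0: [], 1: []}
        frames = []
        for ci, per_stratum in enumerate(sizes):
            lab = f"c{ci}"
            for g, n in enumerate(per_stratum):
                df = random_df(rng, n, cols=("dha", "y"))
                strata[g].append(summarize_df(df, lab, f"g={g}"))
                frames.append(
                    df.assign(
                        g=float(g),
                        **{
                            "g:dha": g * df.dha,
                            f"cohort[c0]": float(ci == 0),
                            f"cohort[c1]": float(ci == 1),
                        },
                    )
                )
        return strata, pd.concat(frames, ignore_index=True)

    def test_matches_concatenation_with_explicit_columns(self, rng):
        strata, concat = self.cells_and_frames(rng)
        design = build_stratified_design(strata, "g", interact_with=["dha"])
        oracle = summarize_df(concat)
        got = design.summary.subset(oracle.variables)
        np.testing.assert_allclose(got.means, oracle.means, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(got.cov, oracle.cov, rtol=1e-10, atol=1e-12)
        # pooled mean of G·X is p1 * mean of X among G=1
        g1 = concat[concat.g == 1.0]
        assert design.summary.mean_of("g:dha") == pytest.approx(
            len(g1) / len(concat) * g1.dha.mean()
        )

    def test_everyone_in_stratum_zero_gives_null_product(self, rng):
        cells = {0: [summarize_df(random_df(rng, 6), "only")]}
        design = build_stratified_design(cells, "g", interact_with=["x"])
        s = design.summary
        assert s.mean_of("g:x") == 0.0
        np.testing.assert_allclose(s.cov[s.index("g:x")], 0.0, atol=1e-15)

    def test_bad_stratum_value_and_small_cell(self, rng):
        good = summarize_df(random_df(rng, 5), "A")
        with pytest.raises(PcssError, match="0/1"):
            build_stratified_design({2: [good]}, "g")
        small = SummarySet(["x", "y"], [0, 0], np.eye(2), 1, "B")
        with pytest.raises(InsufficientCellError, match="insufficient cell size"):
            build_stratified_design({0: [good], 1: [small]}, "g")

    def test_interaction_variable_must_exist(self, rng):
        good = summarize_df(random_df(rng, 5), "A")
        with pytest.raises(PcssError, match="'nope'"):
            build_stratified_design({0: [good]}, "g", interact_with=["nope"])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), k=st.integers(1, 5))
def test_pooling_exactness_associativity_permutation(seed, k):
    """Pooling arbitrary partitions equals summarizing the whole, in any
    order and any grouping; SSTO decomposes as SSG + SSE per pair."""
    r = np.random.default_rng(seed)
    dfs = [random_df(r, int(r.integers(2, 40)), cols=("x", "y", "z")) for _ in range(k)]
    sets = [summarize_df(df, f"c{i}") for i, df in enumerate(dfs)]
    whole = summarize_df(pd.concat(dfs, ignore_index=True))
    pooled = pool_summaries(sets).summary
    np.testing.assert_allclose(pooled.means, whole.means, rtol=1e-10, atol=1e-10)
    np.testing.assert_allclose(pooled.cov, whole.cov, rtol=1e-10, atol=1e-10)

    # permutation invariance
    perm = pool_summaries(sets[::-1]).summary
    np.testing.assert_allclose(perm.cov, pooled.cov, rtol=1e-10, atol=1e-12)

    # associativity: pool first two, then the rest
    if k >= 3:
        first = pool_summaries(sets[:2]).summary
        first.cohort_label = "ab"
        nested = pool_summaries([first, *sets[2:]]).summary
        np.testing.assert_allclose(nested.cov, pooled.cov, rtol=1e-9, atol=1e-10)

    # conservation: SSTO from pooled = SSG + SSE from parts, per pair
    N = whole.n
    ssto = (N - 1) * pooled.cov
    grand = pooled.means
    ssg = sum(s.n * np.outer(s.means - grand, s.means - grand) for s in sets)
    sse = sum((s.n - 1) * s.cov for s in sets)
    np.testing.assert_allclose(ssto, ssg + sse, rtol=1e-9, atol=1e-9)
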