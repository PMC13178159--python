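"""End-to-end analysis workflows built on the module primitives.

These convenience functions wire the standard multi-cohort analysis
together: per-cell summaries -> stratified pooled design -> interaction
F-test, stratified slope fits, per-cohort fits and the IVW meta-analysis
counterpart.  They exist so that examples, the CLI and simulation studies
all execute one shared, tested code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InsufficientSampleSizeError, ZeroVariancePredictorError
from .inference import FTestResult, nested_f_test
from .meta import MetaResult, meta_interaction_test
from .pooling import build_stratified_design
from .regression import (
    FitResult,
    InsufficientSampleSize,
    ModelSpec,
    fit_ols,
    fit_stratified,
)
from .summary import LinearCombo, SummarySet


@dataclass
class InteractionAnalysis:
    """Results of the pooled exact interaction workflow."""

    f_test: FTestResult
    full_fit: FitResult
    reduced_fit: FitResult
    stratified_fits: dict[int, FitResult]
    interaction_term: str


def exact_interaction_analysis(
    strata_cells: Mapping[int, Sequence[SummarySet]],
    outcome: str | LinearCombo,
    exposure: str,
    covariates: Sequence[str] = (),
    stratum_name: str = "carrier",
    ci_level: float = 0.95,
) -> InteractionAnalysis:
    """Exact pooled interaction test plus stratified fits, all from PCSS.

    Builds the stratified pooled design (stratum indicator G, product
    G·exposure, cohort fixed effects), compares the model with the
    product term against the one without by a nested F-test, and fits
    the exposure model separately within each stratum.
    """
    design = build_stratified_design(
        strata_cells, stratum_name, interact_with=[exposure]
    )
    fam = design.indicator_families["cohort"]
    inter = f"{stratum_name}:{exposure}"
    base = [exposure, *covariates, stratum_name, *fam]
    full = fit_ols(
        design, ModelSpec(outcome, [*base, inter], ci_level=ci_level)
    )
    reduced = fit_ols(design, ModelSpec(outcome, base, ci_level=ci_level))
    ftest = nested_f_test(full, reduced)
    strat_fits = fit_stratified(
        strata_cells,
        ModelSpec(outcome, [exposure, *covariates], ci_level=ci_level),
    )
    return InteractionAnalysis(
        f_test=ftest,
        full_fit=full,
        reduced_fit=reduced,
        stratified_fits=strat_fits,
        interaction_term=inter,
    )


def per_cohort_interaction_fits(
    strata_cells: Mapping[int, Sequence[SummarySet]],
    outcome: str | LinearCombo,
    exposure: str,
    covariates: Sequence[str] = (),
    stratum_name: str = "carrier",
) -> dict[str, FitResult | InsufficientSampleSize]:
    """Within-cohort interaction models (no pooling across cohorts).

    Each cohort's own stratum cells are combined into that cohort's
    design with G and G·exposure; cohorts failing the sample-size guard
    come back as markers, ready for :func:`pcssreg.meta.meta_interaction_test`.
    """
    inter = f"{stratum_name}:{exposure}"
    by_cohort: dict[str, dict[int, list[SummarySet]]] = {}
    for g, cells in strata_cells.items():
        for c in cells:
            by_cohort.setdefault(c.cohort_label, {}).setdefault(int(g), []).append(c)
    spec = ModelSpec(outcome, [exposure, *covariates, stratum_name, inter])
    out: dict[str, FitResult | InsufficientSampleSize] = {}
    for label in sorted(by_cohort):
        design = build_stratified_design(
            by_cohort[label], stratum_name, interact_with=[exposure]
        )
        try:
            out[label] = fit_ols(design, spec)
        except (InsufficientSampleSizeError, ZeroVariancePredictorError):
            # one-stratum cohorts have constant G; treat like undersized
            out[label] = InsufficientSampleSize(
                n=design.n, n_params=len(spec.predictors) + 1, cohort_label=label
            )
    return out


def meta_interaction_analysis(
    strata_cells: Mapping[int, Sequence[SummarySet]],
    outcome: str | LinearCombo,
    exposure: str,
    covariates: Sequence[str] = (),
    stratum_name: str = "carrier",
) -> MetaResult:
    """IVW fixed-effects meta-analysis of per-cohort interaction fits."""
    fits = per_cohort_interaction_fits(
        strata_cells, outcome, exposure, covariates, stratum_name
    )
    return meta_interaction_test(fits, f"{stratum_name}:{exposure}")


def max_relative_difference(a: FitResult, b: FitResult) -> float:
    """Worst-case relative discrepancy between two fits of the same model.

    Compares estimates, SEs, RSS, sigma^2, t statistics and p-values on
    matched term names; the divisor is max(1, |reference|) so that
    near-zero quantities are compared absolutely.
    """
    if set(a.terms) != set(b.terms):
        raise ValueError(f"term mismatch: {a.terms} vs {b.terms}")
    idx = [b.terms.index(t) for t in a.terms]

    def rel(x: np.ndarray, y: np.ndarray) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        return float(np.max(np.abs(x - y) / np.maximum(1.0, np.abs(y))))

    return max(
        rel(a.estimates, b.estimates[idx]),
        rel(a.std_errors, b.std_errors[idx]),
        rel(a.t_stats, b.t_stats[idx]),
        rel(a.p_values, b.p_values[idx]),
        rel(a.rss, b.rss),
        rel(a.sigma2, b.sigma2),
        float(abs(a.df_resid - b.df_resid)),
    )
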