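"""Monte-Carlo validation studies on synthetic multi-cohort data.

Four studies certify the method end to end:

* :func:`equivalence_sweep` — the defining exactness claim: over randomized
  multi-cohort configurations, every fitted quantity from the summary-
  statistic path must match row-level least squares to near machine
  precision.
* :func:`type1_error_study` — the interaction F-test rejects at the nominal
  rate when the generating interaction is zero.
* :func:`recovery_study` — stratified slope CIs cover the generating truth
  at the nominal rate and the interaction estimate is unbiased.
* :func:`power_study` — the exact pooled F-test is at least as powerful as
  the IVW meta-analytic z-test under a true interaction.

Replicates whose random design produces an infeasible cell (a cohort x
stratum cell with fewer than 2 rows, where a sample covariance is
undefined) are redrawn: the studies condition on design feasibility, as a
real stratified analysis would.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InsufficientCellError
from .inference import nested_f_test
from .pooling import build_stratified_design
from .regression import ModelSpec, fit_ols, fit_stratified
from .synthetic import (
    TRAILS_DIFF,
    GeneratorConfig,
    fit_ols_ipd,
    generate_cohorts,
    random_multicohort_dataset,
    summarize_ipd,
    summarize_ipd_stratified,
)
from .workflows import (
    max_relative_difference,
    meta_interaction_analysis,
)

_COVARIATES = ("age", "sex", "bmi")


# ---------------------------------------------------------------------------
# Exactness sweep


def equivalence_case(rng: np.random.Generator) -> float:
    """One random configuration; returns the worst relative discrepancy.

    Compares the pooled-summary fit against row-level least squares on
    the full model, the reduced model and (when stratified) the nested
    interaction F statistic and per-stratum fits.
    """
    while True:
        tables, preds, strat = random_multicohort_dataset(rng)
        try:
            if strat:
                cells = summarize_ipd_stratified(tables, "g")
            break
        except InsufficientCellError:
            continue  # redraw: a stratum cell came out with < 2 rows

    worst = 0.0
    if not strat:
        from .pooling import add_group_indicators, pool_summaries

        sets = summarize_ipd(tables)
        pooled = (
            add_group_indicators(sets) if len(sets) > 1 else pool_summaries(sets)
        )
        fam = pooled.indicator_families.get("cohort", [])
        spec = ModelSpec("y", [*preds, *fam])
        fit = fit_ols(pooled, spec)
        ipd = fit_ols_ipd(tables, ModelSpec("y", preds))
        return max_relative_difference(fit, ipd)

    design = build_stratified_design(cells, "g", interact_with=[preds[0]])
    fam = design.indicator_families["cohort"]
    inter = f"g:{preds[0]}"
    full_spec = ModelSpec("y", [*preds, "g", inter, *fam])
    red_spec = ModelSpec("y", [*preds, "g", *fam])
    full = fit_ols(design, full_spec)
    red = fit_ols(design, red_spec)
    ipd_full = fit_ols_ipd(tables, ModelSpec("y", [*preds, "g", inter]))
    ipd_red = fit_ols_ipd(tables, ModelSpec("y", [*preds, "g"]))
    worst = max(
        max_relative_difference(full, ipd_full),
        max_relative_difference(red, ipd_red),
    )
    f_pcss = nested_f_test(full, red)
    f_ipd = nested_f_test(ipd_full, ipd_red)
    worst = max(
        worst,
        abs(f_pcss.f_stat - f_ipd.f_stat) / max(1.0, abs(f_ipd.f_stat)),
        abs(f_pcss.p_value - f_ipd.p_value),
    )
    strat_fits = fit_stratified(cells, ModelSpec("y", preds))
    for g, fit_g in strat_fits.items():
        ipd_g = fit_ols_ipd(tables, ModelSpec("y", preds), where=("g", g))
        worst = max(worst, max_relative_difference(fit_g, ipd_g))
    return worst


def equivalence_sweep(rng: np.random.Generator, n_configs: int = 200) -> float:
    """Worst relative PCSS-vs-IPD discrepancy over random configurations."""
    return max(equivalence_case(rng) for _ in range(n_configs))


# ---------------------------------------------------------------------------
# Interaction-test operating characteristics


def _draw_feasible_cells(rng: np.random.Generator, base: GeneratorConfig):
    """Generate one replicate, redrawing until every cell has n >= 2."""
    while True:
        cfg = replace(base, seed=int(rng.integers(2**31)))
        tables = generate_cohorts(cfg)
        try:
            return tables, summarize_ipd_stratified(tables, "carrier")
        except InsufficientCellError:
            continue


def interaction_pvalue(cells) -> float:
    """Exact pooled interaction F-test p-value for one replicate."""
    design = build_stratified_design(cells, "carrier", interact_with=["dha"])
    fam = design.indicator_families["cohort"]
    base = ["dha", *_COVARIATES, "carrier", *fam]
    full = fit_ols(design, ModelSpec(TRAILS_DIFF, [*base, "carrier:dha"]))
    red = fit_ols(design, ModelSpec(TRAILS_DIFF, base))
    return nested_f_test(full, red).p_value


def type1_error_study(
    rng: np.random.Generator,
    n_reps: int = 2000,
    cohort_sizes: tuple[int, ...] = (300, 200, 60, 40),
) -> float:
    """Rejection rate of the interaction F-test at alpha=0.05 under b_int=0."""
    base = GeneratorConfig(cohort_sizes=cohort_sizes, b_int=0.0)
    hits = 0
    for _ in range(n_reps):
        _, cells = _draw_feasible_cells(rng, base)
        if interaction_pvalue(cells) < 0.05:
            hits += 1
    return hits / n_reps


@dataclass
class RecoveryResult:
    coverage_carrier: float
    coverage_noncarrier: float
    mean_interaction: float
    mc_se_interaction: float
    mean_carrier_slope: float
    mean_noncarrier_slope: float
    n_reps: int


def recovery_study(rng: np.random.Generator, n_reps: int = 500) -> RecoveryResult:
    """CI coverage of stratified slopes and bias of the interaction estimate.

    Generating truth at defaults: DHA slope -0.06 in non-carriers and
    -0.06 + (-0.07) = -0.13 in carriers.
    """
    base = GeneratorConfig()
    truth = {0: base.b_dha, 1: base.carrier_slope}
    covered = {0: 0, 1: 0}
    slopes = {0: np.empty(n_reps), 1: np.empty(n_reps)}
    inter_est = np.empty(n_reps)
    spec = ModelSpec(TRAILS_DIFF, ["dha", *_COVARIATES])
    for r in range(n_reps):
        _, cells = _draw_feasible_cells(rng, base)
        fits = fit_stratified(cells, spec)
        for g in (0, 1):
            lo, hi = fits[g].ci("dha")
            covered[g] += lo <= truth[g] <= hi
            slopes[g][r] = fits[g].estimate("dha")
        design = build_stratified_design(cells, "carrier", interact_with=["dha"])
        fam = design.indicator_families["cohort"]
        full = fit_ols(
            design,
            ModelSpec(
                TRAILS_DIFF, ["dha", *_COVARIATES, "carrier", *fam, "carrier:dha"]
            ),
        )
        inter_est[r] = full.estimate("carrier:dha")
    return RecoveryResult(
        coverage_carrier=covered[1] / n_reps,
        coverage_noncarrier=covered[0] / n_reps,
        mean_interaction=float(inter_est.mean()),
        mc_se_interaction=float(inter_est.std(ddof=1) / np.sqrt(n_reps)),
        mean_carrier_slope=float(slopes[1].mean()),
        mean_noncarrier_slope=float(slopes[0].mean()),
        n_reps=n_reps,
    )


@dataclass
class PowerResult:
    power_exact: float
    power_meta: float
    n_reps: int


def power_study(rng: np.random.Generator, n_reps: int = 500) -> PowerResult:
    """Rejection rates at alpha=0.05: exact pooled F vs IVW meta z.

    Uses the default (unbalanced) cohort sizes and the default true
    interaction b_int = -0.07.
    """
    base = GeneratorConfig()
    hits_exact = hits_meta = 0
    for _ in range(n_reps):
        _, cells = _draw_feasible_cells(rng, base)
        if interaction_pvalue(cells) < 0.05:
            hits_exact += 1
        m = meta_interaction_analysis(cells, TRAILS_DIFF, "dha", _COVARIATES)
        if m.p_value < 0.05:
            hits_meta += 1
    return PowerResult(hits_exact / n_reps, hits_meta / n_reps, n_reps)
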