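"""Exact OLS fitting from summary statistics alone.

Given the pooled means x̄, sample covariance S (divisor n-1) and size n,
the least-squares fit of y on predictors X is recovered without rows:

    slopes    b = S_xx^{-1} s_xy
    intercept b0 = ȳ - x̄' b
    RSS       = (n - 1) (s_yy - s_xy' S_xx^{-1} s_xy)
    Var(b)    = σ² [(n-1) S_xx]^{-1},  σ² = RSS / (n - p - 1)
    Var(b0)   = σ² (1/n + x̄' [(n-1) S_xx]^{-1} x̄)

These are algebraic rearrangements of the normal equations, so every
coefficient, standard error and residual quantity is *identical* to the
fit on the underlying row-level data — not an approximation.  Inference
uses the t distribution with n - p - 1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy import stats

from .errors import (
    InsufficientSampleSizeError,
    PcssError,
    SingularDesignError,
    ZeroVariancePredictorError,
)
from .pooling import PooledSummary, add_group_indicators, pool_summaries
from .summary import LinearCombo, SummarySet, transform_outcome

#: Condition-number threshold on the predictor correlation block.
SINGULARITY_COND = 1e10

INTERCEPT = "(Intercept)"


@dataclass
class ModelSpec:
    """Declarative OLS model: outcome, predictors, identifiability drops.

    ``outcome`` is a variable name or a :class:`LinearCombo` to be derived
    from outcome variables in the summary set.  ``reference_drop`` lists
    predictors to exclude for identifiability; when ``None`` and the data
    carries a complete indicator family among the predictors, the
    lexicographically first indicator of each family is dropped
    automatically (a deterministic reference level).
    """

    outcome: str | LinearCombo
    predictors: Sequence[str]
    reference_drop: Sequence[str] | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        self.predictors = list(self.predictors)
        if len(set(self.predictors)) != len(self.predictors):
            raise PcssError("predictors must be unique")
        if not 0.0 < self.ci_level < 1.0:
            raise PcssError(f"ci_level must be in (0,1), got {self.ci_level}")
        name = self.outcome if isinstance(self.outcome, str) else self.outcome.new_name
        if name in self.predictors:
            raise PcssError(f"outcome {name!r} also appears among predictors")

    @property
    def outcome_name(self) -> str:
        return self.outcome if isinstance(self.outcome, str) else self.outcome.new_name


@dataclass
class FitResult:
    """OLS estimates with t-based inference, intercept first."""

    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    rss: float
    sigma2: float
    df_resid: int
    t_stats: np.ndarray
    p_values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    outcome: str
    ci_level: float = 0.95

    def index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise PcssError(f"term {term!r} not in fit: {self.terms}") from None

    def estimate(self, term: str) -> float:
        return float(self.estimates[self.index(term)])

    def se(self, term: str) -> float:
        return float(self.std_errors[self.index(term)])

    def ci(self, term: str) -> tuple[float, float]:
        i = self.index(term)
        return float(self.ci_low[i]), float(self.ci_high[i])

    def p_value(self, term: str) -> float:
        return float(self.p_values[self.index(term)])

    @property
    def n_params(self) -> int:
        return len(self.terms)

    def predict(self, values: Mapping[str, float]) -> float:
        """Point prediction ŷ at a supplied covariate vector."""
        yhat = float(self.estimates[0])
        for term, est in zip(self.terms[1:], self.estimates[1:]):
            yhat += float(est) * float(values[term])
        return yhat


@dataclass
class InsufficientSampleSize:
    """Marker returned for per-cohort fits barred by the n > p + 1 guard."""

    n: int
    n_params: int
    cohort_label: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Insufficient Sample Size (n = {self.n})"


def _resolve_terms(
    data: SummarySet | PooledSummary, spec: ModelSpec
) -> tuple[SummarySet, list[str], str]:
    s = data.summary if isinstance(data, PooledSummary) else data
    if isinstance(spec.outcome, LinearCombo):
        if spec.outcome.new_name not in s.variables:
            s = transform_outcome(s, spec.outcome)
        yname = spec.outcome.new_name
    else:
        yname = spec.outcome
        s.index(yname)

    predictors = list(spec.predictors)
    if spec.reference_drop is not None:
        drops = list(spec.reference_drop)
        for d in drops:
            if d not in predictors:
                raise PcssError(f"reference_drop names unknown predictor {d!r}")
    else:
        drops = []
        fams = data.indicator_families if isinstance(data, PooledSummary) else {}
        for names in fams.values():
            if names and all(nm in predictors for nm in names):
                drops.append(min(names))
    kept = [p for p in predictors if p not in set(drops)]
    for p in kept:
        s.index(p)
    return s, kept, yname


def fit_ols(data: SummarySet | PooledSummary, spec: ModelSpec) -> FitResult:
    """Exact OLS fit of ``spec`` from summary statistics.

    Raises ``InsufficientSampleSizeError`` when n <= p + 1,
    ``ZeroVariancePredictorError`` for a constant predictor, and
    ``SingularDesignError`` (naming a dependent column) when the
    predictor correlation block has condition number above 1e10.
    """
    s, kept, yname = _resolve_terms(data, spec)
    p = len(kept)
    n = s.n
    if n <= p + 1:
        raise InsufficientSampleSizeError(
            f"insufficient sample size: n={n} with {p} predictors "
            f"requires n > {p + 1}"
        )
    if p == 0:
        raise PcssError("no predictors retained after reference drops")

    xi = [s.index(v) for v in kept]
    yi = s.index(yname)
    Sxx = s.cov[np.ix_(xi, xi)]
    sxy = s.cov[np.ix_(xi, [yi])].ravel()
    syy = float(s.cov[yi, yi])
    xbar = s.means[xi]
    ybar = float(s.means[yi])

    d = np.diag(Sxx).copy()
    zero = np.flatnonzero(d <= 0)
    if zero.size:
        raise ZeroVariancePredictorError(
            f"predictor {kept[int(zero[0])]!r} has zero sample variance"
        )
    scale = 1.0 / np.sqrt(d)
    corr = Sxx * np.outer(scale, scale)
    if np.linalg.cond(corr) > SINGULARITY_COND:
        w, V = np.linalg.eigh(corr)
        culprit = kept[int(np.argmax(np.abs(V[:, 0])))]
        raise SingularDesignError(
            f"predictor block numerically singular (condition number "
            f"{np.linalg.cond(corr):.3g}); column {culprit!r} is linearly "
            "dependent on the others"
        )

    # Cholesky of the covariance block: stable solve without explicit inverse
    try:
        cho = scipy.linalg.cho_factor(Sxx, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise SingularDesignError(str(exc)) from exc
    slopes = scipy.linalg.cho_solve(cho, sxy)
    Sxx_inv = scipy.linalg.cho_solve(cho, np.eye(p))

    intercept = ybar - xbar @ slopes
    rss = max(float((n - 1) * (syy - sxy @ slopes)), 0.0)
    df_resid = n - p - 1
    sigma2 = rss / df_resid

    se_slopes = np.sqrt(sigma2 * np.diag(Sxx_inv) / (n - 1))
    se_int = math.sqrt(sigma2 * (1.0 / n + xbar @ Sxx_inv @ xbar / (n - 1)))

    estimates = np.concatenate([[intercept], slopes])
    std_errors = np.concatenate([[se_int], se_slopes])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(std_errors > 0, estimates / std_errors, np.inf * np.sign(estimates))
    p_values = 2.0 * stats.t.sf(np.abs(t_stats), df_resid)
    tq = stats.t.ppf(0.5 + spec.ci_level / 2.0, df_resid)
    return FitResult(
        terms=[INTERCEPT, *kept],
        estimates=estimates,
        std_errors=std_errors,
        rss=rss,
        sigma2=sigma2,
        df_resid=df_resid,
        t_stats=t_stats,
        p_values=p_values,
        ci_low=estimates - tq * std_errors,
        ci_high=estimates + tq * std_errors,
        n=n,
        outcome=yname,
        ci_level=spec.ci_level,
    )


def fit_stratified(
    strata_sets: Mapping[int, Sequence[SummarySet]],
    spec: ModelSpec,
    family_name: str = "cohort",
) -> dict[int, FitResult]:
    """Fit ``spec`` separately within each stratum, pooled across cohorts.

    Each stratum's cohort cells are pooled with cohort-membership
    indicators (appended to the predictor list and reference-dropped
    automatically); errors are re-raised with the stratum attached.
    """
    out: dict[int, FitResult] = {}
    for g in sorted(strata_sets, key=int):
        cells = list(strata_sets[g])
        labels = {c.cohort_label for c in cells}
        try:
            if len(labels) > 1:
                pooled = add_group_indicators(cells, family_name)
                fam = pooled.indicator_families[family_name]
                spec_g = ModelSpec(
                    spec.outcome,
                    [*spec.predictors, *fam],
                    spec.reference_drop,
                    spec.ci_level,
                )
                out[int(g)] = fit_ols(pooled, spec_g)
            else:
                out[int(g)] = fit_ols(pool_summaries(cells), spec)
        except PcssError as exc:
            raise type(exc)(f"stratum {g}: {exc}") from exc
    return out


def fit_per_cohort(
    cells: Sequence[SummarySet], spec: ModelSpec
) -> dict[str, FitResult | InsufficientSampleSize]:
    """Unpooled per-cohort fits; undersized cohorts yield a marker.

    Mirrors the reporting convention of multi-cohort tables where a
    cohort too small for the model is flagged rather than fitted.
    """
    out: dict[str, FitResult | InsufficientSampleSize] = {}
    for cell in cells:
        try:
            out[cell.cohort_label] = fit_ols(cell, spec)
        except InsufficientSampleSizeError:
            out[cell.cohort_label] = InsufficientSampleSize(
                n=cell.n,
                n_params=len(spec.predictors) + 1,
                cohort_label=cell.cohort_label,
            )
    return out
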