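"""Nested-model F-tests and Wald intervals from summary-statistic fits.

Because the summary-statistic OLS fit reproduces the row-level RSS and
residual degrees of freedom exactly, the classical nested-model ANOVA
F-test is available with no further information:

    F = [(RSS_reduced - RSS_full) / q] / [RSS_full / df_full],

with q the number of constrained parameters.  This is how an interaction
term is tested: full model with stratum indicator and product terms
versus the reduced model without the products.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import NonNestedModelError, PcssError
from .regression import FitResult


@dataclass
class FTestResult:
    """Nested-model comparison: F statistic, df pair and p-value."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    term_names: list[str]


def nested_f_test(full: FitResult, reduced: FitResult) -> FTestResult:
    """ANOVA F-test of ``full`` against the nested ``reduced`` model.

    Both fits must share the outcome and sample; the reduced model's
    terms must be a strict subset of the full model's.  Tiny negative
    numerators from floating-point cancellation are clamped to zero.
    """
    if full.outcome != reduced.outcome:
        raise NonNestedModelError(
            f"outcomes differ: {full.outcome!r} vs {reduced.outcome!r}"
        )
    if full.n != reduced.n:
        raise PcssError(f"sample sizes differ: {full.n} vs {reduced.n}")
    extra = sorted(set(reduced.terms) - set(full.terms))
    if extra:
        raise NonNestedModelError(
            f"models not nested; reduced-only terms: {extra}"
        )
    tested = [t for t in full.terms if t not in set(reduced.terms)]
    q = reduced.df_resid - full.df_resid
    if q <= 0:
        raise NonNestedModelError(
            "full model has no extra parameters relative to reduced"
        )
    num = (reduced.rss - full.rss) / q
    den = full.rss / full.df_resid
    f = num / den
    if f < -1e-12:
        raise PcssError(f"negative F statistic {f!r}: models inconsistent")
    f = max(f, 0.0)
    p = float(stats.f.sf(f, q, full.df_resid))
    return FTestResult(
        f_stat=float(f),
        df_num=int(q),
        df_den=int(full.df_resid),
        p_value=p,
        term_names=tested,
    )


def wald_intervals(
    fit: FitResult, level: float = 0.95
) -> dict[str, tuple[float, float]]:
    """Per-term t-based confidence intervals ``estimate ± t_q · SE``."""
    if not 0.0 < level < 1.0:
        raise PcssError(f"confidence level must be in (0,1), got {level}")
    tq = float(stats.t.ppf(0.5 + level / 2.0, fit.df_resid))
    lo = fit.estimates - tq * fit.std_errors
    hi = fit.estimates + tq * fit.std_errors
    return {t: (float(l), float(h)) for t, l, h in zip(fit.terms, lo, hi)}
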