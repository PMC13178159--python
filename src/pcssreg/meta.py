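"""Fixed-effects inverse-variance meta-analysis of per-cohort fits.

The conventional alternative to exact pooling: fit the model separately
on each cohort, then average the per-cohort coefficients with weights
w_j = 1 / SE_j².  The pooled estimate is sum(w_j b_j) / sum(w_j) with
SE 1 / sqrt(sum w_j) and normal (z) inference.  Unlike the exact pooled
fit this is an approximation — it ignores cross-cohort information when
estimating nuisance coefficients and drops cohorts too small to fit —
which is precisely the contrast the package is built to quantify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import PcssError
from .regression import FitResult, InsufficientSampleSize

logger = logging.getLogger(__name__)


@dataclass
class MetaResult:
    """IVW fixed-effects pooled coefficient with z inference."""

    estimate: float
    std_error: float
    z_stat: float
    p_value: float
    weights: np.ndarray  # normalized, sums to 1
    k_studies: int
    labels: list[str]


def ivw_fixed_effects(
    studies: Sequence[tuple[float, float]],
    labels: Sequence[str] | None = None,
) -> MetaResult:
    """Pool (estimate, SE) pairs with inverse-variance weights."""
    if not studies:
        raise PcssError("meta-analysis requires at least one study")
    labels = list(labels) if labels is not None else [
        f"study{i + 1}" for i in range(len(studies))
    ]
    est = np.array([b for b, _ in studies], dtype=float)
    se = np.array([s for _, s in studies], dtype=float)
    bad = np.flatnonzero(~(se > 0))
    if bad.size:
        raise PcssError(
            f"nonpositive standard error for study {labels[int(bad[0])]!r}: "
            f"{se[int(bad[0])]!r}"
        )
    w_raw = 1.0 / se**2
    pooled = float(w_raw @ est / w_raw.sum())
    pooled_se = float(1.0 / np.sqrt(w_raw.sum()))
    z = pooled / pooled_se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return MetaResult(
        estimate=pooled,
        std_error=pooled_se,
        z_stat=float(z),
        p_value=p,
        weights=w_raw / w_raw.sum(),
        k_studies=len(studies),
        labels=labels,
    )


def meta_interaction_test(
    per_cohort_fits: Mapping[str, FitResult | InsufficientSampleSize],
    term: str,
) -> MetaResult:
    """IVW z-test of one coefficient (typically the interaction) across cohorts.

    Cohorts whose fit was barred by the sample-size guard are skipped
    with a logged warning — they still contribute to the exact pooled
    analysis, an asymmetry worth keeping visible when comparing methods.
    """
    studies: list[tuple[float, float]] = []
    labels: list[str] = []
    for label, fit in per_cohort_fits.items():
        if isinstance(fit, InsufficientSampleSize):
            logger.warning(
                "meta-analysis: skipping cohort %r (insufficient sample "
                "size, n=%d for %d parameters)",
                label,
                fit.n,
                fit.n_params,
            )
            continue
        studies.append((fit.estimate(term), fit.se(term)))
        labels.append(label)
    if not studies:
        raise PcssError(f"no cohort provides an estimate of {term!r}")
    return ivw_fixed_effects(studies, labels)
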