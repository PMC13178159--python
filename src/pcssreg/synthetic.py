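"""Synthetic multi-cohort data emulating the DHA / APOE-ε4 cognition study.

Generates row-level records for four cohorts patterned on the Framingham
Offspring, Generation 3, Omni 1 and Omni 2 samples: red-blood-cell DHA
(% of total fatty acids), APOE-ε4 carrier status, a compact demographic
covariate set, and Trail Making Test part A / part B times in minutes.
The modelled outcome is the part B minus part A difference (executive
function; larger = more impaired), generated as

    diff = b0 + cohort effect + b_dha·DHA + b_int·carrier·DHA
           + covariate effects + Gaussian noise.

Default cohort sizes, carrier prevalences and DHA moments follow the
published cohort descriptives; the default DHA slopes (-0.06 in
non-carriers, -0.06 + -0.07 = -0.13 in carriers, minutes per 1% DHA)
make the published stratified associations the generating truth.

The module also provides the row-level (IPD) least-squares oracle used
throughout the test suite to certify that summary-statistic fits are
exact, plus a generic random multi-cohort generator for equivalence
sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientCellError, PcssError
from .regression import (
    INTERCEPT,
    FitResult,
    ModelSpec,
)
from .errors import InsufficientSampleSizeError, SingularDesignError
from .summary import LinearCombo, SummarySet


@dataclass
class CovariateSpec:
    """One generated covariate: sampling distribution and outcome effect.

    ``dist`` is one of ``"normal"`` (params: mean, sd),
    ``"truncated-normal"`` (mean, sd, low, high) or ``"bernoulli"`` (p).
    ``effect`` is the additive contribution per unit to the outcome
    difference, in minutes.
    """

    name: str
    dist: str
    params: tuple[float, ...]
    effect: float = 0.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "normal":
            mu, sd = self.params
            return rng.normal(mu, sd, n)
        if self.dist == "truncated-normal":
            mu, sd, lo, hi = self.params
            a, b = (lo - mu) / sd, (hi - mu) / sd
            return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
        if self.dist == "bernoulli":
            (p,) = self.params
            return (rng.random(n) < p).astype(float)
        raise PcssError(f"unknown covariate distribution {self.dist!r}")


def default_covariates() -> list[CovariateSpec]:
    """Age / sex / BMI calibrated to the pooled cohort descriptives."""
    return [
        CovariateSpec("age", "truncated-normal", (58.9, 5.5, 50.0, 70.0), 0.02),
        CovariateSpec("sex", "bernoulli", (0.543,), -0.05),
        CovariateSpec("bmi", "normal", (28.6, 5.7), 0.01),
    ]


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic four-cohort emulation.

    Defaults encode the published cohort structure: sizes 1201/778/135/44,
    APOE-ε4 carrier prevalences 27.6/26.2/21.5/13.6%, per-cohort DHA
    means (SDs) 4.8(1.4)/4.4(1.3)/5.2(1.4)/5.1(1.0) % of total FA.  The
    DHA main effect ``b_dha`` and carrier-specific addition ``b_int``
    are in minutes of part B - part A per 1% DHA.
    """

    cohort_labels: tuple[str, ...] = ("Offspring", "Gen3", "Omni1", "Omni2")
    cohort_sizes: tuple[int, ...] = (1201, 778, 135, 44)
    carrier_prevalence: tuple[float, ...] = (0.276, 0.262, 0.215, 0.136)
    dha_mean: tuple[float, ...] = (4.8, 4.4, 5.2, 5.1)
    dha_sd: tuple[float, ...] = (1.4, 1.3, 1.4, 1.0)
    covariates: list[CovariateSpec] = field(default_factory=default_covariates)
    b_dha: float = -0.06
    b_int: float = -0.07
    intercept: float = -0.16
    cohort_effects: tuple[float, ...] = (0.0, -0.2, 0.4, 0.0)
    noise_sd: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.cohort_labels)
        for name in ("cohort_sizes", "carrier_prevalence", "dha_mean", "dha_sd", "cohort_effects"):
            if len(getattr(self, name)) != k:
                raise PcssError(
                    f"{name} has length {len(getattr(self, name))}, "
                    f"expected {k} (one per cohort)"
                )
        if any(n < 2 for n in self.cohort_sizes):
            raise PcssError("cohort sizes must be >= 2")
        if any(not 0.0 < p < 1.0 for p in self.carrier_prevalence):
            raise PcssError("carrier prevalences must be in (0, 1)")
        if any(sd <= 0 for sd in self.dha_sd):
            raise PcssError("DHA standard deviations must be positive")
        if self.noise_sd < 0:
            raise PcssError("noise_sd must be nonnegative")

    @property
    def carrier_slope(self) -> float:
        """Generating DHA slope among carriers: b_dha + b_int."""
        return self.b_dha + self.b_int


@dataclass
class CohortTable:
    """Row-level records for one cohort (oracle path only)."""

    label: str
    data: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.data)


# columns that always lead the generated tables, before covariates
_BASE_COLS = ("carrier", "dha")
_TMT_COLS = ("trails_a", "trails_b")

TRAILS_DIFF = LinearCombo(
    weights={"trails_b": 1.0, "trails_a": -1.0}, new_name="trails_diff"
)


def generate_cohorts(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[CohortTable]:
    """Draw the synthetic cohorts; reproducible given ``config.seed``.

    Part A time is lognormal with median 0.5 min; only the B - A
    difference enters any model, so part A's law is a free presentation
    choice.  Part A is raised where needed so both raw times stay
    positive, which leaves the difference untouched.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tables: list[CohortTable] = []
    for j, label in enumerate(config.cohort_labels):
        n = config.cohort_sizes[j]
        carrier = (rng.random(n) < config.carrier_prevalence[j]).astype(float)
        # physical floor: DHA is a percentage of total fatty acids
        dha = np.maximum(rng.normal(config.dha_mean[j], config.dha_sd[j], n), 0.05)
        cols: dict[str, np.ndarray] = {"carrier": carrier, "dha": dha}
        diff = (
            config.intercept
            + config.cohort_effects[j]
            + config.b_dha * dha
            + config.b_int * carrier * dha
        )
        for cv in config.covariates:
            x = cv.sample(n, rng)
            cols[cv.name] = x
            diff = diff + cv.effect * x
        if config.noise_sd > 0:
            diff = diff + rng.normal(0.0, config.noise_sd, n)
        trails_a = rng.lognormal(math.log(0.5), 0.4, n)
        trails_a = np.maximum(trails_a, 0.05 - diff)  # keep part B time positive
        cols["trails_a"] = trails_a
        cols["trails_b"] = trails_a + diff
        tables.append(CohortTable(label, pd.DataFrame(cols)))
    return tables


def summarize_ipd(
    tables: Sequence[CohortTable],
    variables: Sequence[str] | None = None,
) -> list[SummarySet]:
    """One SummarySet per cohort (means, n-1 covariance, n)."""
    out = []
    for t in tables:
        if t.n < 2:
            raise InsufficientCellError(
                f"insufficient cell size: cohort {t.label!r} has n={t.n} < 2"
            )
        out.append(SummarySet.from_dataframe(t.data, t.label, "", variables))
    return out


def summarize_ipd_stratified(
    tables: Sequence[CohortTable],
    stratify_by: str,
    variables: Sequence[str] | None = None,
    drop_small_cells: bool = False,
) -> dict[int, list[SummarySet]]:
    """Per-cohort, per-stratum cells keyed by the 0/1 stratum value.

    The stratifying column must be binary.  A cell with n < 2 aborts
    with an "insufficient cell size" error unless ``drop_small_cells``,
    in which case the cell (cohort absent from that stratum) is skipped.
    """
    out: dict[int, list[SummarySet]] = {0: [], 1: []}
    for t in tables:
        col = t.data[stratify_by]
        values = sorted(set(col.astype(int)))
        if not set(values) <= {0, 1}:
            raise PcssError(
                f"stratifying variable {stratify_by!r} must be 0/1, "
                f"found values {values}"
            )
        if variables is None:
            cell_vars = [c for c in t.data.columns if c != stratify_by]
        else:
            cell_vars = [c for c in variables if c != stratify_by]
        for g in values:
            rows = t.data[col.astype(int) == g]
            if len(rows) < 2:
                if drop_small_cells:
                    continue
                raise InsufficientCellError(
                    f"insufficient cell size: cohort {t.label!r}, "
                    f"{stratify_by}={g} has n={len(rows)} < 2"
                )
            out[g].append(
                SummarySet.from_dataframe(
                    rows, t.label, f"{stratify_by}={g}", cell_vars
                )
            )
    return out


# ---------------------------------------------------------------------------
# Row-level least-squares oracle


def _design_columns(df: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a predictor name on rows; ``a:b`` means the product a*b."""
    if name in df.columns:
        return df[name].to_numpy(dtype=float)
    if ":" in name:
        a, b = name.split(":", 1)
        return _design_columns(df, a) * _design_columns(df, b)
    raise PcssError(f"cannot build design column {name!r} from the table")


def fit_ols_ipd(
    tables: Sequence[CohortTable],
    spec: ModelSpec,
    add_cohort_effects: bool = True,
    where: tuple[str, float] | None = None,
) -> FitResult:
    """Textbook least squares on the concatenated row-level design matrix.

    This is the package's reference implementation: it never touches the
    summary-statistic code path (the fit is computed from the explicit
    n x (p+1) design matrix), so agreement with :func:`fit_ols` on pooled
    summaries certifies exactness.  Cohort membership dummies named like
    the pooled path's indicators are appended when more than one cohort
    is present, dropping the lexicographically first label.  ``where``
    restricts rows, e.g. ``("carrier", 1)`` for a stratum fit; predictor
    names may use ``a:b`` for row-wise products.
    """
    frames = []
    for t in tables:
        df = t.data.copy()
        df["__cohort__"] = t.label
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    if where is not None:
        col, val = where
        data = data[data[col].astype(float) == float(val)].reset_index(drop=True)

    if isinstance(spec.outcome, LinearCombo):
        y = np.full(len(data), float(spec.outcome.constant))
        for name, w in spec.outcome.weights.items():
            y = y + float(w) * data[name].to_numpy(dtype=float)
        yname = spec.outcome.new_name
    else:
        y = data[spec.outcome].to_numpy(dtype=float)
        yname = spec.outcome

    labels = sorted(data["__cohort__"].unique())
    terms = list(spec.predictors)
    cols = [_design_columns(data, t) for t in terms]
    if add_cohort_effects and len(labels) > 1:
        for lab in labels[1:]:  # first label is the reference level
            terms.append(f"cohort[{lab}]")
            cols.append((data["__cohort__"] == lab).to_numpy(dtype=float))

    n = len(data)
    p = len(terms)
    if n <= p + 1:
        raise InsufficientSampleSizeError(
            f"insufficient sample size: n={n} with {p} predictors"
        )
    X = np.column_stack([np.ones(n), *cols])
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e14:
        raise SingularDesignError("row-level design matrix is singular")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - p - 1
    sigma2 = rss / df_resid
    XtX_inv = np.linalg.inv(XtX)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_values = 2.0 * stats.t.sf(np.abs(t_stats), df_resid)
    tq = stats.t.ppf(0.5 + spec.ci_level / 2.0, df_resid)
    return FitResult(
        terms=[INTERCEPT, *terms],
        estimates=beta,
        std_errors=se,
        rss=rss,
        sigma2=sigma2,
        df_resid=df_resid,
        t_stats=t_stats,
        p_values=p_values,
        ci_low=beta - tq * se,
        ci_high=beta + tq * se,
        n=n,
        outcome=yname,
        ci_level=spec.ci_level,
    )


# ---------------------------------------------------------------------------
# Generic random configurations for equivalence sweeps


def random_multicohort_dataset(
    rng: np.random.Generator,
    n_cohorts: int | None = None,
    n_predictors: int | None = None,
    size_range: tuple[int, int] = (30, 2000),
    with_stratum: bool | None = None,
) -> tuple[list[CohortTable], list[str], bool]:
    """Draw an arbitrary multi-cohort dataset for exactness sweeps.

    Cohort count, sizes, predictor count, predictor correlation, effect
    sizes and the presence of a binary stratum variable are all
    randomized.  Returns (tables, predictor names, has_stratum); the
    outcome column is ``"y"`` and the stratum column ``"g"``.
    """
    k = int(n_cohorts) if n_cohorts is not None else int(rng.integers(1, 7))
    m = int(n_predictors) if n_predictors is not None else int(rng.integers(1, 11))
    strat = bool(rng.random() < 0.5) if with_stratum is None else with_stratum
    pred_names = [f"x{i + 1}" for i in range(m)]
    # random SPD predictor covariance, shared across cohorts
    Af = rng.normal(size=(m, m))
    Sigma = Af @ Af.T + m * np.eye(m)
    L = np.linalg.cholesky(Sigma)
    beta = rng.normal(0.0, 1.0, m)
    b_g = rng.normal(0.0, 0.5)
    b_gx = rng.normal(0.0, 0.5)
    tables = []
    for j in range(k):
        n = int(rng.integers(size_range[0], size_range[1] + 1))
        Xm = rng.normal(size=(n, m)) @ L.T + rng.normal(0.0, 2.0, m)
        cols = {nm: Xm[:, i] for i, nm in enumerate(pred_names)}
        y = rng.normal(0.0, 1.0) + Xm @ beta + rng.normal(0.0, 1.0, n)
        if strat:
            # keep both cells comfortably populated
            g = (rng.random(n) < rng.uniform(0.25, 0.75)).astype(float)
            y = y + b_g * g + b_gx * g * Xm[:, 0]
            cols["g"] = g
        cols["y"] = y
        tables.append(CohortTable(f"c{j + 1:02d}", pd.DataFrame(cols)))
    return tables, pred_names, strat
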