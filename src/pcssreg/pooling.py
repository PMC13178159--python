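"""Exact pooling of per-cohort / per-stratum summary statistics.

The engine is the ANOVA decomposition of cross-products.  For any pair of
variables X1, X2 split into k groups with group means x̄_1j, x̄_2j, group
sizes n_j and within-group sample covariances cov_j:

    SSG = sum_j n_j (x̄_1j - x̿_1)(x̄_2j - x̿_2)      (between groups)
    SSE = sum_j (n_j - 1) cov_j                        (within groups)
    SSTO = SSG + SSE

and the pooled sample covariance is SSTO / (N - 1) with N = sum_j n_j.
Pooling per-group summary sets this way reproduces, exactly, the summary
set of the concatenated row-level data — so any downstream OLS fit is
identical to the fit on pooled individual-level records.

Two augmentations are built from the same algebra without any rows:

* cohort-membership 0/1 indicators (fixed cohort effects), and
* a binary stratum indicator G together with products G·X, which turn
  per-stratum summaries into an exact interaction design.

Both exploit that an indicator is *constant within each cell*, so its
within-cell covariances vanish and a constant column appended per cell
pools into exactly the moments of the row-level 0/1 column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DuplicateLabelError,
    InsufficientCellError,
    PcssError,
    UnknownVariableError,
    VariableMismatchError,
)
from .summary import SummarySet


@dataclass
class PooledSummary:
    """A pooled :class:`SummarySet` plus provenance and synthesis flags.

    ``indicator_families`` maps a family name (e.g. ``"cohort"``) to the
    ordered list of synthesized 0/1 indicator variables; ``interaction_terms``
    maps each synthesized product variable to the ``(indicator, variable)``
    pair it multiplies; ``stratum_variable`` names the binary stratum
    indicator when the design was built stratified.
    """

    summary: SummarySet
    provenance: list[tuple[str, str, int]]
    indicator_families: dict[str, list[str]] = field(default_factory=dict)
    interaction_terms: dict[str, tuple[str, str]] = field(default_factory=dict)
    stratum_variable: str | None = None

    # passthrough so fitting code can take SummarySet or PooledSummary
    @property
    def variables(self) -> list[str]:
        return self.summary.variables

    @property
    def means(self) -> np.ndarray:
        return self.summary.means

    @property
    def cov(self) -> np.ndarray:
        return self.summary.cov

    @property
    def n(self) -> int:
        return self.summary.n


def _check_poolable(sets: Sequence[SummarySet]) -> None:
    if not sets:
        raise PcssError("pool_summaries requires at least one summary set")
    ref = sets[0].variables
    for s in sets[1:]:
        if s.variables != ref:
            extra = sorted(set(s.variables) - set(ref))
            missing = sorted(set(ref) - set(s.variables))
            raise VariableMismatchError(
                f"variable lists differ for {s.label}: "
                f"missing {missing}, unexpected {extra} "
                f"(order must match too: {ref} vs {s.variables})"
            )
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise DuplicateLabelError(f"duplicate (cohort, stratum) labels: {dup}")


def pool_summaries(sets: Sequence[SummarySet]) -> PooledSummary:
    """Combine summary sets into the exact summary of the concatenation.

    Pooled mean of each variable is the size-weighted mean; each pooled
    covariance entry is (SSG + SSE) / (N - 1).  Pooling a single set
    returns it unchanged (SSG = 0).
    """
    _check_poolable(sets)
    prov = [(s.cohort_label, s.stratum_label, s.n) for s in sets]
    if len(sets) == 1:
        return PooledSummary(sets[0].copy(), prov)

    ns = np.array([s.n for s in sets], dtype=float)
    N = ns.sum()
    M = np.stack([s.means for s in sets])  # k x m
    grand = ns @ M / N
    D = M - grand
    ssg = (ns[:, None] * D).T @ D
    sse = sum((s.n - 1) * s.cov for s in sets)
    cov = (ssg + sse) / (N - 1)
    pooled = SummarySet(
        list(sets[0].variables), grand, cov, int(N), cohort_label="pooled"
    )
    return PooledSummary(pooled, prov)


def append_constant(s: SummarySet, name: str, value: float) -> SummarySet:
    """Append a within-cell constant column (mean=value, zero covariance)."""
    if name in s.variables:
        raise PcssError(f"variable {name!r} already present in {s.label}")
    m = s.nvar
    A = np.vstack([np.eye(m), np.zeros(m)])
    c = np.zeros(m + 1)
    c[-1] = float(value)
    return s.apply_linear_map(A, c, [*s.variables, name])


def indicator_name(family: str, label: str) -> str:
    return f"{family}[{label}]"


def add_group_indicators(
    sets: Sequence[SummarySet], family_name: str = "cohort"
) -> PooledSummary:
    """Pool with one 0/1 membership indicator per contributing cohort.

    Within each cell the indicator is constant (1 for the owning cohort,
    0 elsewhere), so appending constants per cell and pooling yields the
    exact moments of explicit row-level 0/1 columns: indicator mean
    n_j/N, covariance with a variable X of n_j (x̄_j - x̿)/(N-1),
    variance N p_j (1-p_j)/(N-1), and cross-covariance between distinct
    indicators -N p_j p_k / (N-1).
    """
    _check_poolable(sets)
    labels = sorted({s.cohort_label for s in sets})
    names = [indicator_name(family_name, lab) for lab in labels]
    augmented = []
    for s in sets:
        cur = s
        for lab, name in zip(labels, names):
            cur = append_constant(cur, name, 1.0 if s.cohort_label == lab else 0.0)
        augmented.append(cur)
    pooled = pool_summaries(augmented)
    pooled.indicator_families[family_name] = names
    return pooled


def _augment_stratum_cell(
    s: SummarySet,
    g: int,
    stratum_name: str,
    interact_with: Sequence[str],
) -> SummarySet:
    """Add G = g and products G·X to one stratum cell, exactly.

    Within the cell G is the constant g, hence G·X = g·X as a linear map
    of the cell's variables: in the G=1 stratum each product duplicates
    X's summary entries; in the G=0 stratum it is identically zero.
    """
    if stratum_name in s.variables:
        raise PcssError(f"variable {stratum_name!r} already present")
    for x in interact_with:
        s.index(x)  # raises UnknownVariableError with context
    m = s.nvar
    rows = [np.eye(m), np.zeros((1, m))]
    consts = [np.zeros(m), np.array([float(g)])]
    names = [*s.variables, stratum_name]
    for x in interact_with:
        e = np.zeros((1, m))
        e[0, s.index(x)] = float(g)
        rows.append(e)
        consts.append(np.zeros(1))
        names.append(f"{stratum_name}:{x}")
    A = np.vstack(rows)
    c = np.concatenate(consts)
    return s.apply_linear_map(A, c, names, stratum_label=f"{stratum_name}={g}")


def build_stratified_design(
    strata: Mapping[int, Sequence[SummarySet]],
    stratum_name: str,
    interact_with: Sequence[str] = (),
    family_name: str = "cohort",
) -> PooledSummary:
    """Pool per-stratum cells into an exact interaction design.

    ``strata`` maps the binary stratum value (0/1) to that stratum's
    per-cohort summary cells.  The result contains the original
    variables, the stratum indicator, each requested product
    ``<stratum_name>:<X>`` and cohort membership indicators, and equals
    the summary of concatenated row-level data carrying explicit G and
    G·X columns.  A cohort may be absent from one stratum; a present
    cell with n < 2 is rejected ("insufficient cell size") because a
    covariance with divisor n-1 is undefined there.
    """
    bad = [g for g in strata if int(g) not in (0, 1)]
    if bad:
        raise PcssError(f"stratum values must be 0/1, got {sorted(bad)}")
    cells: list[SummarySet] = []
    for g in sorted(strata, key=int):
        for s in strata[g]:
            if s.n < 2:
                raise InsufficientCellError(
                    f"insufficient cell size: cohort {s.cohort_label!r}, "
                    f"{stratum_name}={int(g)} has n={s.n} < 2"
                )
            cells.append(
                _augment_stratum_cell(s, int(g), stratum_name, interact_with)
            )
    if not cells:
        raise PcssError("no stratum cells supplied")
    pooled = add_group_indicators(cells, family_name)
    pooled.stratum_variable = stratum_name
    pooled.interaction_terms = {
        f"{stratum_name}:{x}": (stratum_name, x) for x in interact_with
    }
    return pooled
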