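"""Pre-computed summary statistics (PCSS) container and outcome transforms.

A :class:`SummarySet` carries everything ordinary least squares needs from
one cohort (or one cohort x stratum cell): the variable names, their sample
means, the sample covariance matrix (divisor ``n - 1``) and the sample size.
No row-level data is stored, which is the point — these statistics are
non-individually-identifiable and freely shareable, yet sufficient to
reproduce the exact OLS fit that row-level access would give.

Because means and covariances are closed under linear maps, a derived
outcome such as a time difference between two test components can be
appended to a summary set exactly, without ever seeing a row
(:func:`transform_outcome`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import NameCollisionError, UnknownVariableError

#: Relative tolerance for covariance symmetry (vs. the largest |entry|).
SYMMETRY_RTOL = 1e-10
#: Smallest eigenvalue may be >= -PSD_RTOL * largest eigenvalue.
PSD_RTOL = 1e-8


@dataclass
class SummarySet:
    """Means, sample covariance (divisor n-1) and size for one data cell.

    Parameters
    ----------
    variables
        Ordered, unique variable names.
    means
        Per-variable sample means, same order as ``variables``.
    cov
        Square sample covariance matrix with divisor ``n - 1``.
    n
        Number of observations the statistics were computed on.
    cohort_label, stratum_label
        Free-text provenance; ``stratum_label`` is empty for unstratified
        summaries and conventionally ``"<var>=<value>"`` for stratum cells.
    """

    variables: list[str]
    means: np.ndarray
    cov: np.ndarray
    n: int
    cohort_label: str = ""
    stratum_label: str = ""

    def __post_init__(self) -> None:
        self.variables = [str(v) for v in self.variables]
        self.means = np.asarray(self.means, dtype=float).reshape(-1)
        self.cov = np.asarray(self.cov, dtype=float)
        self.n = int(self.n)
        m = len(self.variables)
        if self.means.shape != (m,):
            raise ValueError(
                f"means has length {self.means.shape[0]}, expected {m}"
            )
        if self.cov.shape != (m, m):
            raise ValueError(
                f"cov has shape {self.cov.shape}, expected ({m}, {m})"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def nvar(self) -> int:
        return len(self.variables)

    @property
    def label(self) -> tuple[str, str]:
        return (self.cohort_label, self.stratum_label)

    def index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise UnknownVariableError(
                f"unknown variable {name!r}; available: {self.variables}"
            ) from None

    def mean_of(self, name: str) -> float:
        return float(self.means[self.index(name)])

    def var_of(self, name: str) -> float:
        i = self.index(name)
        return float(self.cov[i, i])

    def cov_of(self, a: str, b: str) -> float:
        return float(self.cov[self.index(a), self.index(b)])

    def copy(self) -> "SummarySet":
        return SummarySet(
            list(self.variables),
            self.means.copy(),
            self.cov.copy(),
            self.n,
            self.cohort_label,
            self.stratum_label,
        )

    def subset(self, names: Sequence[str]) -> "SummarySet":
        """Restrict (and reorder) to ``names``, keeping n and labels."""
        idx = [self.index(v) for v in names]
        return SummarySet(
            [self.variables[i] for i in idx],
            self.means[idx],
            self.cov[np.ix_(idx, idx)],
            self.n,
            self.cohort_label,
            self.stratum_label,
        )

    def drop(self, names: Iterable[str]) -> "SummarySet":
        gone = set(names)
        for g in gone:
            self.index(g)  # raise on unknown
        keep = [v for v in self.variables if v not in gone]
        return self.subset(keep)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df,
        cohort_label: str = "",
        stratum_label: str = "",
        variables: Sequence[str] | None = None,
    ) -> "SummarySet":
        """Summarize a row-level table (pandas DataFrame) into a SummarySet.

        Covariance uses divisor ``n - 1`` (pandas default).
        """
        cols = list(variables) if variables is not None else list(df.columns)
        sub = df[cols].astype(float)
        means = sub.mean().to_numpy()
        cov = sub.cov().to_numpy()  # ddof=1
        return cls(cols, means, cov, len(sub), cohort_label, stratum_label)

    def apply_linear_map(
        self,
        weights: np.ndarray,
        constants: np.ndarray,
        names: Sequence[str],
        stratum_label: str | None = None,
    ) -> "SummarySet":
        """Return the summary of ``Z = A X + c`` for a linear map ``A``.

        ``weights`` is the (new x old) coefficient matrix ``A`` and
        ``constants`` the offset ``c``.  Exactness follows from linearity of
        the mean and bilinearity of covariance; this is the single primitive
        behind outcome transforms and stratified-design augmentation.
        """
        A = np.asarray(weights, dtype=float)
        c = np.asarray(constants, dtype=float).reshape(-1)
        means = A @ self.means + c
        cov = A @ self.cov @ A.T
        return SummarySet(
            list(names),
            means,
            cov,
            self.n,
            self.cohort_label,
            self.stratum_label if stratum_label is None else stratum_label,
        )


@dataclass
class LinearCombo:
    """A derived variable ``new = sum_i weights[v_i] * v_i + constant``."""

    weights: Mapping[str, float]
    new_name: str
    constant: float = 0.0

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("LinearCombo requires at least one weight")


def validate_summary(s: SummarySet) -> list[str]:
    """Report every structural violation in ``s`` (empty list == valid).

    Checks: n >= 2, unique variable names, covariance symmetry (relative
    tolerance ``SYMMETRY_RTOL``), nonnegative diagonal, and positive
    semi-definiteness up to ``PSD_RTOL`` of the largest eigenvalue.  This is
    a reporting operation — callers decide whether violations are fatal.
    """
    out: list[str] = []
    if s.n < 2:
        out.append(f"sample size n={s.n} < 2")
    seen: dict[str, int] = {}
    for v in s.variables:
        seen[v] = seen.get(v, 0) + 1
    dups = sorted(v for v, k in seen.items() if k > 1)
    if dups:
        out.append(f"duplicate variable names: {dups}")

    M = s.cov
    scale = max(1.0, float(np.max(np.abs(M))) if M.size else 0.0)
    asym = np.abs(M - M.T)
    if M.size and float(asym.max()) > SYMMETRY_RTOL * scale:
        i, j = np.unravel_index(int(asym.argmax()), asym.shape)
        out.append(
            "covariance not symmetric: "
            f"cov[{s.variables[i]!r},{s.variables[j]!r}]={M[i, j]!r} vs "
            f"cov[{s.variables[j]!r},{s.variables[i]!r}]={M[j, i]!r} "
            f"(|diff|={float(asym.max()):.3g})"
        )

    diag = np.diag(M)
    for i in np.flatnonzero(diag < -SYMMETRY_RTOL * scale):
        out.append(
            f"negative variance for {s.variables[int(i)]!r}: {diag[int(i)]!r}"
        )

    if M.size:
        sym = 0.5 * (M + M.T)
        eig = np.linalg.eigvalsh(sym)
        lo, hi = float(eig[0]), float(eig[-1])
        if lo < -PSD_RTOL * max(hi, 1e-300):
            out.append(
                "covariance not positive semi-definite: smallest eigenvalue "
                f"{lo:.6g} (largest {hi:.6g})"
            )
    return out


def transform_outcome(s: SummarySet, combo: LinearCombo) -> SummarySet:
    """Append the derived variable defined by ``combo`` to ``s`` exactly.

    The appended mean is ``sum_i a_i mean_i + c``; its covariance with any
    existing variable W is ``sum_i a_i Cov(v_i, W)`` and its variance is
    ``a' Cov a``.  Existing entries and ``n`` are untouched, so the result
    is identical to summarizing row-level data with the derived column
    added.
    """
    if combo.new_name in s.variables:
        raise NameCollisionError(
            f"variable {combo.new_name!r} already exists in the summary set"
        )
    a = np.zeros(s.nvar)
    for name, w in combo.weights.items():
        a[s.index(name)] = float(w)

    m = s.nvar
    A = np.vstack([np.eye(m), a])
    c = np.zeros(m + 1)
    c[-1] = float(combo.constant)
    return s.apply_linear_map(A, c, [*s.variables, combo.new_name])
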