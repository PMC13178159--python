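"""Reading and writing PCSS files and result artifacts.

Canonical format is a self-describing JSON document (one per cohort x
stratum cell); a CSV triplet dialect (``means.csv`` / ``cov.csv`` /
``meta.csv`` in one directory) is accepted for spreadsheet-origin PCSS.
Floats are serialized at full round-trip precision (Python's shortest
repr), so write-then-read reproduces a summary set bit-exactly.

The covariance divisor is pinned in the file (``cov_divisor: "n-1"``);
files declaring any other convention are refused rather than silently
rescaled.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .errors import SchemaError, SummaryValidationError
from .summary import SYMMETRY_RTOL, SummarySet, validate_summary

SCHEMA_VERSION = "1.0"
COV_DIVISOR = "n-1"


def _symmetrize(s: SummarySet) -> SummarySet:
    """Average away sub-tolerance asymmetry; hard error above tolerance."""
    M = s.cov
    scale = max(1.0, float(np.max(np.abs(M))) if M.size else 0.0)
    asym = float(np.max(np.abs(M - M.T))) if M.size else 0.0
    if asym > SYMMETRY_RTOL * scale:
        raise SummaryValidationError(
            f"covariance asymmetry {asym:.3g} exceeds tolerance "
            f"{SYMMETRY_RTOL * scale:.3g}; refusing to symmetrize"
        )
    s.cov = 0.5 * (M + M.T)
    return s


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise SchemaError(msg)


def summary_to_dict(s: SummarySet, provenance: Mapping[str, str] | None = None) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "cohort_label": s.cohort_label,
        "stratum_label": s.stratum_label,
        "n": int(s.n),
        "variables": list(s.variables),
        "means": [float(x) for x in s.means],
        "cov": [[float(x) for x in row] for row in s.cov],
        "cov_divisor": COV_DIVISOR,
        "provenance": dict(provenance or {}),
    }


def summary_from_dict(doc: Mapping[str, Any]) -> SummarySet:
    for key in ("n", "variables", "means", "cov", "cov_divisor"):
        _check(key in doc, f"missing required field {key!r}")
    _check(
        doc["cov_divisor"] == COV_DIVISOR,
        f"unknown cov_divisor {doc['cov_divisor']!r}; this format stores "
        f"sample covariances with divisor {COV_DIVISOR!r}",
    )
    variables = doc["variables"]
    _check(
        isinstance(variables, list) and all(isinstance(v, str) for v in variables),
        "field 'variables' must be a list of strings",
    )
    m = len(variables)
    means = doc["means"]
    _check(
        isinstance(means, list) and len(means) == m,
        f"field 'means' must list {m} numbers (one per variable), "
        f"got {len(means) if isinstance(means, list) else type(means).__name__}",
    )
    cov = doc["cov"]
    _check(isinstance(cov, list), "field 'cov' must be a list of rows")
    _check(
        len(cov) == m and all(isinstance(r, list) and len(r) == m for r in cov),
        f"field 'cov' must be a {m}x{m} matrix matching the variable list, "
        f"got {len(cov)} rows",
    )
    _check(isinstance(doc["n"], int) and doc["n"] >= 2, "field 'n' must be an integer >= 2")
    s = SummarySet(
        variables,
        np.array(means, dtype=float),
        np.array(cov, dtype=float),
        doc["n"],
        str(doc.get("cohort_label", "")),
        str(doc.get("stratum_label", "")),
    )
    s = _symmetrize(s)
    violations = validate_summary(s)
    if violations:
        raise SummaryValidationError("; ".join(violations))
    return s


def write_pcss(
    s: SummarySet, path: str | Path, provenance: Mapping[str, str] | None = None
) -> Path:
    """Write a summary set as canonical JSON (round-trip precision)."""
    path = Path(path)
    path.write_text(
        json.dumps(summary_to_dict(s, provenance), indent=1) + "\n"
    )
    return path


def write_pcss_csv(s: SummarySet, directory: str | Path) -> Path:
    """Write the CSV-triplet dialect into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "means.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["variable", "mean"])
        for v, m in zip(s.variables, s.means):
            w.writerow([v, repr(float(m))])
    with open(d / "cov.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["variable", *s.variables])
        for v, row in zip(s.variables, s.cov):
            w.writerow([v, *(repr(float(x)) for x in row)])
    with open(d / "meta.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["key", "value"])
        for k, v in [
            ("schema_version", SCHEMA_VERSION),
            ("cohort_label", s.cohort_label),
            ("stratum_label", s.stratum_label),
            ("n", str(int(s.n))),
            ("cov_divisor", COV_DIVISOR),
        ]:
            w.writerow([k, v])
    return d


def _read_pcss_csv(d: Path) -> SummarySet:
    for fname in ("means.csv", "cov.csv", "meta.csv"):
        _check((d / fname).exists(), f"CSV triplet missing {fname} in {d}")
    with open(d / "meta.csv", newline="") as fh:
        rows = list(csv.reader(fh))
    _check(rows and rows[0] == ["key", "value"], "meta.csv must have header key,value")
    meta = {k: v for k, v in rows[1:]}
    with open(d / "means.csv", newline="") as fh:
        rows = list(csv.reader(fh))
    _check(rows and rows[0] == ["variable", "mean"], "means.csv must have header variable,mean")
    variables = [r[0] for r in rows[1:]]
    means = [float(r[1]) for r in rows[1:]]
    with open(d / "cov.csv", newline="") as fh:
        rows = list(csv.reader(fh))
    _check(
        bool(rows) and rows[0][1:] == variables,
        "cov.csv header must list the variables in means.csv order",
    )
    _check(
        [r[0] for r in rows[1:]] == variables,
        "cov.csv row labels must match the variable list",
    )
    cov = [[float(x) for x in r[1:]] for r in rows[1:]]
    try:
        n = int(meta.get("n", ""))
    except ValueError:
        raise SchemaError(f"meta.csv field 'n' is not an integer: {meta.get('n')!r}")
    return summary_from_dict(
        {
            "schema_version": meta.get("schema_version", SCHEMA_VERSION),
            "cohort_label": meta.get("cohort_label", ""),
            "stratum_label": meta.get("stratum_label", ""),
            "n": n,
            "variables": variables,
            "means": means,
            "cov": cov,
            "cov_divisor": meta.get("cov_divisor", ""),
            "provenance": {},
        }
    )


def read_pcss(path: str | Path) -> SummarySet:
    """Read a PCSS file (JSON) or CSV-triplet directory into a SummarySet."""
    path = Path(path)
    if path.is_dir():
        return _read_pcss_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path} is not valid JSON: {exc}") from exc
    _check(isinstance(doc, dict), f"{path}: top level must be a JSON object")
    return summary_from_dict(doc)


def write_cohort_csv(table, path: str | Path) -> Path:
    """Write synthetic row-level records as plain CSV (header row first)."""
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


def fit_result_to_dict(fit) -> dict:
    return {
        "outcome": fit.outcome,
        "n": int(fit.n),
        "df_resid": int(fit.df_resid),
        "rss": float(fit.rss),
        "sigma2": float(fit.sigma2),
        "ci_level": float(fit.ci_level),
        "terms": [
            {
                "term": t,
                "estimate": float(fit.estimates[i]),
                "std_error": float(fit.std_errors[i]),
                "t_stat": float(fit.t_stats[i]),
                "p_value": float(fit.p_values[i]),
                "ci_low": float(fit.ci_low[i]),
                "ci_high": float(fit.ci_high[i]),
            }
            for i, t in enumerate(fit.terms)
        ],
    }


def fit_result_tsv(fit) -> str:
    lines = ["term\testimate\tstd_error\tt_stat\tp_value\tci_low\tci_high"]
    for row in fit_result_to_dict(fit)["terms"]:
        lines.append(
            "\t".join(
                [
                    row["term"],
                    *(
                        repr(row[k])
                        for k in (
                            "estimate",
                            "std_error",
                            "t_stat",
                            "p_value",
                            "ci_low",
                            "ci_high",
                        )
                    ),
                ]
            )
        )
    return "\n".join(lines) + "\n"
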