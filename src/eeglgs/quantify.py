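"""Scalar quantifiers of LGS code matrices and feature-table assembly.

Each code matrix is reduced to three numbers: the Shannon entropy of its
code-value histogram (bits), the natural-log entropy of the same
histogram (nats; exactly Shannon x ln 2), and the largest singular value
of the code matrix viewed as a real matrix. Eight operators x three
quantifiers give a 24-dimensional feature vector per (subject, segment,
band).

``logenergy_mode="sum_log_squares"`` switches the second quantifier to
the wavelet-style log-energy form sum(log(s^2)) over nonzero codes; the
histogram-entropy form is the default.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import ContractError, IncompleteFeaturesError
from .lgs import CodeMatrix, builtin_patterns

#: Quantifier order within each operator's column triple.
QUANTIFIERS = ("shannon", "logenergy", "svd")

#: Metadata columns preceding the feature columns of a feature table.
META_COLUMNS = ("subject_id", "segment", "band", "label")


def code_histogram(cm: CodeMatrix) -> np.ndarray:
    """Empirical probabilities of the 256 code values (sums to 1)."""
    if cm.codes.size == 0:
        raise ContractError("empty code matrix")
    counts = np.bincount(cm.codes.ravel(), minlength=256)
    return counts / counts.sum()


def shannon_entropy(cm: CodeMatrix) -> float:
    """Histogram entropy in bits: -sum p log2 p, zero terms contribute 0."""
    p = code_histogram(cm)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def log_energy_entropy(cm: CodeMatrix, mode: str = "eq_hist") -> float:
    """Histogram entropy in nats: -sum p ln p.

    This is the natural-log counterpart of :func:`shannon_entropy` and
    is exactly proportional to it (factor ln 2). ``mode="sum_log_squares"``
    instead returns sum(ln(c^2)) over nonzero codes, the conventional
    signal-processing log-energy entropy, offered as an extension.
    """
    if mode == "sum_log_squares":
        c = cm.codes.ravel().astype(np.float64)
        c = c[c != 0]
        return float(np.log(c**2).sum())
    p = code_histogram(cm)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def top_singular_value(cm: CodeMatrix) -> float:
    """Largest singular value of the code matrix as a real matrix."""
    if cm.codes.size == 0:
        raise ContractError("empty code matrix")
    return float(linalg.svdvals(cm.codes.astype(np.float64))[0])


def singular_values(cm: CodeMatrix, k: int | None = None) -> np.ndarray:
    """Descending singular values; optionally only the leading k."""
    s = linalg.svdvals(cm.codes.astype(np.float64))
    return s if k is None else s[:k]


def quantify(cm: CodeMatrix, logenergy_mode: str = "eq_hist") -> dict[str, float]:
    """All three quantifiers of one code matrix, keyed by quantifier name."""
    return {
        "shannon": shannon_entropy(cm),
        "logenergy": log_energy_entropy(cm, mode=logenergy_mode),
        "svd": top_singular_value(cm),
    }


def feature_columns(operators: Iterable[str] | None = None) -> list[str]:
    """Deterministic feature column order: operator alphabetical x quantifier."""
    if operators is None:
        operators = [p.name for p in builtin_patterns()]
    return [f"{op}_{q}" for op in sorted(operators) for q in QUANTIFIERS]


def build_features(
    code_matrices: Iterable[CodeMatrix],
    labels: Mapping[str, str] | None = None,
    logenergy_mode: str = "eq_hist",
) -> pd.DataFrame:
    """Assemble a tidy feature table from complete 8-operator code sets.

    Rows are (subject, segment, band) samples sorted lexicographically;
    columns are the four metadata columns followed by 24 feature columns
    named ``<operator>_<quantifier>``. A sample missing any operator
    raises :class:`IncompleteFeaturesError` listing the gaps.
    """
    expected = sorted(p.name for p in builtin_patterns())
    cells: dict[tuple[str, int, str], dict] = {}
    for cm in code_matrices:
        key = (cm.subject_id, cm.segment_index, cm.band)
        cell = cells.setdefault(key, {"label": cm.class_label, "ops": {}})
        cell["ops"][cm.operator] = cm
    if not cells:
        raise ContractError("no code matrices supplied")

    gaps = []
    for key, cell in cells.items():
        missing = [op for op in expected if op not in cell["ops"]]
        if missing:
            gaps.append(f"{key}: missing {missing}")
    if gaps:
        raise IncompleteFeaturesError("; ".join(gaps))

    rows = []
    for (subject, segment, band), cell in sorted(cells.items()):
        label = cell["label"]
        if labels is not None and subject in labels:
            label = labels[subject]
        row: dict = {
            "subject_id": subject, "segment": segment, "band": band, "label": label,
        }
        for op in expected:
            for q, v in quantify(cell["ops"][op], logenergy_mode=logenergy_mode).items():
                row[f"{op}_{q}"] = v
        rows.append(row)
    cols = list(META_COLUMNS) + feature_columns(expected)
    return pd.DataFrame(rows, columns=cols).reset_index(drop=True)


def per_quantifier_table(table: pd.DataFrame, quantifier: str) -> pd.DataFrame:
    """Slice a combined table down to one quantifier's 8 operator columns."""
    if quantifier not in QUANTIFIERS:
        raise ContractError(f"unknown quantifier {quantifier!r}")
    cols = [c for c in table.columns if c in META_COLUMNS or c.endswith(f"_{quantifier}")]
    return table[cols].copy()


def write_feature_tables(table: pd.DataFrame, outdir, prefix: str = "features") -> list:
    """Write the combined table plus one CSV per band; returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    combined = outdir / f"{prefix}_combined.csv"
    table.to_csv(combined, index=False)
    paths.append(combined)
    for band, sub in table.groupby("band", sort=True):
        p = outdir / f"{prefix}_{band}.csv"
        sub.to_csv(p, index=False)
        paths.append(p)
    return paths
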