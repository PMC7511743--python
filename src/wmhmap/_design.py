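"""Design-matrix construction with treatment contrasts (level-0 baseline).

All regression models in this package share the same design convention: an
intercept column, continuous covariates entered as-is, k-level factors
expanded into (k-1) dummy columns against the lowest level, and pairwise
interactions formed as elementwise products of the expanded columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Term", "ModelSpec", "DesignMatrix", "build_design"]


@dataclass(frozen=True)
class Term:
    """A single model term: a column name plus how to code it."""

    name: str
    kind: str = "continuous"  # "continuous" | "factor"

    def __post_init__(self):
        if self.kind not in ("continuous", "factor"):
            raise ValueError(f"unknown term kind {self.kind!r}")


@dataclass
class ModelSpec:
    """Response plus ordered covariate terms and interaction pairs."""

    response: str
    terms: list
    interactions: list = field(default_factory=list)

    def coerced_terms(self) -> list[Term]:
        return [t if isinstance(t, Term) else Term(str(t)) for t in self.terms]


@dataclass
class DesignMatrix:
    X: np.ndarray                 # n x p, float64, first column intercept
    names: list[str]              # p column labels
    term_columns: dict[str, list[int]]  # term label -> column indices

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _factor_columns(values: pd.Series, name: str):
    levels = np.unique(values.to_numpy())
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has a single level; design would be rank deficient")
    baseline = levels[0]
    cols, labels = [], []
    for lvl in levels[1:]:
        cols.append((values.to_numpy() == lvl).astype(float))
        lab = lvl
        if isinstance(lab, (float, np.floating)) and float(lab).is_integer():
            lab = int(lab)
        labels.append(f"{name}[{lab}]")
    return cols, labels, baseline


def build_design(table: pd.DataFrame, terms: Sequence, interactions: Sequence = (),
                 add_intercept: bool = True, check_rank: bool = True) -> DesignMatrix:
    """Assemble the n x p design matrix from a covariate table.

    ``terms`` may contain :class:`Term` objects or plain strings (treated as
    continuous). ``interactions`` is a sequence of (name_a, name_b) pairs;
    each pair expands into products of every coded column of a with every
    coded column of b.
    """
    terms = [t if isinstance(t, Term) else Term(str(t)) for t in terms]
    n = len(table)
    cols: list[np.ndarray] = []
    names: list[str] = []
    term_columns: dict[str, list[int]] = {}
    expanded: dict[str, tuple[list[np.ndarray], list[str]]] = {}

    if add_intercept:
        cols.append(np.ones(n))
        names.append("Intercept")
        term_columns["Intercept"] = [0]

    for term in terms:
        if term.name not in table.columns:
            raise KeyError(f"term {term.name!r} not in table")
        vals = table[term.name]
        if vals.isna().any():
            raise ValueError(f"missing values in column {term.name!r}; filter first")
        if term.kind == "continuous":
            tcols = [vals.to_numpy(dtype=float)]
            tlabels = [term.name]
        else:
            tcols, tlabels, _ = _factor_columns(vals, term.name)
        expanded[term.name] = (tcols, tlabels)
        idx = list(range(len(cols), len(cols) + len(tcols)))
        cols.extend(tcols)
        names.extend(tlabels)
        term_columns[term.name] = idx

    for a, b in interactions:
        for side in (a, b):
            if side not in expanded:
                if side not in table.columns:
                    raise KeyError(f"interaction term {side!r} not in table")
                expanded[side] = ([table[side].to_numpy(dtype=float)], [side])
        acols, alabels = expanded[a]
        bcols, blabels = expanded[b]
        label = f"{a}:{b}"
        idx = []
        for ac, al in zip(acols, alabels):
            for bc, bl in zip(bcols, blabels):
                idx.append(len(cols))
                cols.append(ac * bc)
                names.append(f"{al}:{bl}")
        term_columns[label] = idx

    X = np.column_stack(cols) if cols else np.empty((n, 0))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in design matrix")
    if check_rank and X.shape[1]:
        _check_full_rank(X, names)
    return DesignMatrix(X=X, names=names, term_columns=term_columns)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming (nearly) collinear columns if X is rank deficient."""
    _, r, piv = _qr_pivot(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if X.shape[1] > len(diag):
        bad += [names[piv[i]] for i in range(len(diag), X.shape[1])]
    if bad:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}")


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv
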