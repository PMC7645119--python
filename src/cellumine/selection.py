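"""Filter feature selection: one-way ANOVA F scores per descriptor,
Benjamini-Hochberg FDR adjustment, and top-K retention."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import FeatureMatrix, project_columns

__all__ = [
    "FeatureScore",
    "SelectionState",
    "anova_f",
    "bh_adjust",
    "select_k_best",
    "apply_selection",
    "write_score_table",
]


@dataclass(frozen=True)
class FeatureScore:
    name: str
    f_stat: float
    p_value: float
    q_value: float
    rank: int  # 1-based by descending F


@dataclass
class SelectionState:
    """Ordered kept column names plus the K/alpha used to derive them."""

    columns: list[str]
    k: int
    alpha: float
    scores: list[FeatureScore]

    def __post_init__(self) -> None:
        if self.k != len(self.columns):
            raise ValueError("k must equal the number of kept columns")

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "k": self.k,
            "alpha": self.alpha,
            "scores": [vars(s) for s in self.scores],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SelectionState":
        return cls(list(d["columns"]), int(d["k"]), float(d["alpha"]),
                   [FeatureScore(**s) for s in d["scores"]])


def _group_layout(labels: Sequence[str]) -> list[np.ndarray]:
    labels_arr = np.asarray(labels, dtype=object)
    classes = sorted(set(labels))
    return [np.flatnonzero(labels_arr == c) for c in classes]


def anova_f(column: Sequence[float], labels: Sequence[str]) -> tuple[float, float]:
    """One-way ANOVA F statistic and upper-tail p-value for one column.

    F = (SSB / (g - 1)) / (SSW / (n - g)). Degenerate cases follow the
    documented contract: SSW = 0 with SSB > 0 gives (inf, 0); SSB = 0
    (including constant columns) gives (0, 1).
    """
    x = np.asarray(column, dtype=float)
    groups = _group_layout(labels)
    g, n = len(groups), len(x)
    if g < 2:
        raise ValueError("need at least 2 classes")
    if n <= g:
        raise ValueError("need more samples than classes")
    if len(labels) != n:
        raise ValueError("labels length does not match column length")
    f, p = _f_and_p(x[:, None], groups, n, g)
    return float(f[0]), float(p[0])


def _f_and_p(
    X: np.ndarray, groups: list[np.ndarray], n: int, g: int
) -> tuple[np.ndarray, np.ndarray]:
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for rows in groups:
        gx = X[rows]
        gm = gx.mean(axis=0)
        ssb += len(rows) * (gm - grand) ** 2
        ssw += ((gx - gm) ** 2).sum(axis=0)
    # constant columns: SSB is numerically ~0 -> force the exact contract
    constant = np.ptp(X, axis=0) == 0
    ssb[constant] = 0.0
    ssw[constant] = 0.0
    f = np.empty(X.shape[1])
    p = np.empty(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        zero_b = ssb == 0
        zero_w = ssw == 0
        regular = ~zero_b & ~zero_w
        f[zero_b] = 0.0
        p[zero_b] = 1.0
        f[zero_w & ~zero_b] = np.inf
        p[zero_w & ~zero_b] = 0.0
        f[regular] = (ssb[regular] / (g - 1)) / (ssw[regular] / (n - g))
        p[regular] = stats.f.sf(f[regular], g - 1, n - g)
    return f, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, in original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_k_best(
    train: FeatureMatrix,
    labels: Sequence[str],
    k: int | str = "auto",
    alpha: float = 0.05,
    min_features: int = 10,
) -> SelectionState:
    """Score every column with the ANOVA F-test and keep the K best.

    ``k="auto"`` keeps the number of columns whose BH-adjusted p-value is
    below ``alpha`` (never fewer than ``min_features``, capped at the column
    count). Ties in F are broken by original column order.
    """
    n, m = train.shape
    groups = _group_layout(labels)
    if len(labels) != n:
        raise ValueError("labels length does not match feature rows")
    if len(groups) < 2:
        raise ValueError("need at least 2 classes")
    if n <= len(groups):
        raise ValueError("need more samples than classes")
    f, p = _f_and_p(train.data, groups, n, len(groups))
    q = bh_adjust(p)
    if k == "auto":
        k_val = int(np.count_nonzero(q < alpha))
        k_val = max(k_val, min(min_features, m))
    else:
        k_val = int(k)
        if not 1 <= k_val <= m:
            raise ValueError(f"k={k_val} outside [1, {m}]")
    # stable sort on -F keeps original column order among ties
    order = np.argsort(-f, kind="stable")
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    kept = sorted(order[:k_val])  # kept columns stay in matrix order
    scores = [
        FeatureScore(train.columns[j], float(f[j]), float(p[j]), float(q[j]),
                     int(rank[j]))
        for j in range(m)
    ]
    return SelectionState([train.columns[j] for j in kept], k_val, alpha, scores)


def apply_selection(state: SelectionState, m: FeatureMatrix) -> FeatureMatrix:
    """Project a matrix onto the selected columns."""
    out = project_columns(m, state.columns)
    out.provenance[-1] = {"op": "select_k_best", "k": state.k, "alpha": state.alpha}
    return out


def write_score_table(state: SelectionState, path: str | Path) -> None:
    """TSV: name, F, p, q, kept flag."""
    kept = set(state.columns)
    rows = [
        {"name": s.name, "F": s.f_stat, "p": s.p_value, "q": s.q_value,
         "kept": s.name in kept}
        for s in state.scores
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
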