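"""Independent reference implementations used as test oracles.

These deliberately use naive loops / textbook recurrences, not the
vectorized code paths under test.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from Bio.Align import substitution_matrices

from cellumine.descriptors import (
    AA,
    CT_CLASSES,
    CTD_ATTRIBUTES,
    GAAC_GROUPS,
    _PAAC_HYDROPHOBICITY,
    _PAAC_HYDROPHILICITY,
    _PAAC_SIDECHAIN_MASS,
)


# --- descriptor oracles (brute-force counting) -----------------------------

def bf_aac(seq: str) -> np.ndarray:
    return np.array([sum(1 for c in seq if c == a) / len(seq) for a in AA])


def bf_dpc(seq: str) -> np.ndarray:
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    return np.array(
        [sum(1 for p in pairs if p == a + b) / len(pairs) for a in AA for b in AA]
    )


def _group_of(c: str, groups) -> int:
    for gi, members in enumerate(groups):
        if c in members:
            return gi
    raise KeyError(c)


def bf_gaac(seq: str) -> np.ndarray:
    groups = [m for _, m in GAAC_GROUPS]
    mapped = [_group_of(c, groups) for c in seq]
    return np.array([mapped.count(g) / len(seq) for g in range(5)])


def bf_gdpc(seq: str) -> np.ndarray:
    groups = [m for _, m in GAAC_GROUPS]
    mapped = [_group_of(c, groups) for c in seq]
    pairs = list(zip(mapped[:-1], mapped[1:]))
    return np.array(
        [pairs.count((a, b)) / len(pairs) for a in range(5) for b in range(5)]
    )


def bf_ctdc(seq: str) -> np.ndarray:
    out = []
    for _, groups in CTD_ATTRIBUTES:
        mapped = [_group_of(c, groups) for c in seq]
        out.extend(mapped.count(g) / len(seq) for g in range(3))
    return np.array(out)


def bf_ctdt(seq: str) -> np.ndarray:
    out = []
    for _, groups in CTD_ATTRIBUTES:
        mapped = [_group_of(c, groups) for c in seq]
        pairs = list(zip(mapped[:-1], mapped[1:]))
        for a, b in ((0, 1), (0, 2), (1, 2)):
            n = sum(1 for x, y in pairs if (x, y) == (a, b) or (x, y) == (b, a))
            out.append(n / len(pairs))
    return np.array(out)


def bf_ctdd(seq: str) -> np.ndarray:
    out = []
    L = len(seq)
    for _, groups in CTD_ATTRIBUTES:
        mapped = [_group_of(c, groups) for c in seq]
        for g in range(3):
            positions = [i + 1 for i, m in enumerate(mapped) if m == g]
            if not positions:
                out.extend([0.0] * 5)
                continue
            m = len(positions)
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                occurrence = max(1, math.ceil(frac * m))
                out.append(positions[occurrence - 1] / L * 100.0)
    return np.array(out)


def bf_conjoint_triad(seq: str) -> np.ndarray:
    mapped = [_group_of(c, CT_CLASSES) for c in seq]
    triples = list(zip(mapped[:-2], mapped[1:-1], mapped[2:]))
    return np.array(
        [
            triples.count((i, j, k)) / len(triples)
            for i in range(7)
            for j in range(7)
            for k in range(7)
        ]
    )


def bf_paac(seq: str, lam: int, w: float) -> np.ndarray:
    """Loop-based type-1 pseudo-AAC from the raw property tables."""
    scales = []
    for table in (_PAAC_HYDROPHOBICITY, _PAAC_HYDROPHILICITY, _PAAC_SIDECHAIN_MASS):
        vals = [table[a] for a in AA]
        mean = sum(vals) / 20
        std = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20)
        scales.append({a: (table[a] - mean) / std for a in AA})
    L = len(seq)
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            a, b = seq[i], seq[i + k]
            total += sum((s[a] - s[b]) ** 2 for s in scales) / 3
        thetas.append(total / (L - k))
    freqs = [sum(1 for c in seq if c == a) / L for a in AA]
    denom = 1.0 + w * sum(thetas)
    return np.array([f / denom for f in freqs] + [w * t / denom for t in thetas])


# --- alignment oracles ------------------------------------------------------

def blosum62() -> dict:
    mat = substitution_matrices.load("BLOSUM62")
    return {(a, b): float(mat[a, b]) for a in AA for b in AA}


def gotoh_local(a: str, b: str, sub: dict, open_: float, ext: float) -> float:
    """Textbook three-matrix affine-gap local alignment (O(nm) loops)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_, E[i][j - 1] - ext)
            F[i][j] = max(H[i - 1][j] - open_, F[i - 1][j] - ext)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + sub[(a[i - 1], b[j - 1])], E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


def exhaustive_local(a: str, b: str, sub: dict, open_: float, ext: float) -> float:
    """Enumerate every local alignment of tiny sequences: all substring
    pairs, each aligned by exhaustive recursion over edit paths."""

    def best_global(x: str, y: str) -> float:
        def rec(i: int, j: int, last: str) -> float:
            if i == len(x) and j == len(y):
                return 0.0
            best = float("-inf")
            if i < len(x) and j < len(y):
                best = max(best, sub[(x[i], y[j])] + rec(i + 1, j + 1, "M"))
            if i < len(x):
                cost = ext if last == "D" else open_
                best = max(best, -cost + rec(i + 1, j, "D"))
            if j < len(y):
                cost = ext if last == "I" else open_
                best = max(best, -cost + rec(i, j + 1, "I"))
            return best

        return rec(0, 0, "")

    best = 0.0
    for qs, qe in product(range(len(a) + 1), repeat=2):
        if qe <= qs:
            continue
        for ts, te in product(range(len(b) + 1), repeat=2):
            if te <= ts:
                continue
            best = max(best, best_global(a[qs:qe], b[ts:te]))
    return best


# --- statistics oracle ------------------------------------------------------

def naive_anova_f(column, labels) -> float:
    """Two-loop sum-of-squares one-way ANOVA F."""
    classes = sorted(set(labels))
    grand = sum(column) / len(column)
    ssb = ssw = 0.0
    for c in classes:
        vals = [x for x, l in zip(column, labels) if l == c]
        mean = sum(vals) / len(vals)
        ssb += len(vals) * (mean - grand) ** 2
        ssw += sum((v - mean) ** 2 for v in vals)
    df1 = len(classes) - 1
    df2 = len(column) - len(classes)
    return (ssb / df1) / (ssw / df2)
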