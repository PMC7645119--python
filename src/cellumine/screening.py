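"""Translated homology screening of assembled contigs.

Contigs are six-frame translated, stop-split peptides are aligned against a
reference protein set with exact affine-gap Smith-Waterman (BLOSUM62 by
default), raw scores are converted to bits with Karlin-Altschul parameters,
and hits above a configurable bit cut-off are reported. A second filter
shortlists candidates by read coverage and a stricter bit floor.

Scores are exact local-alignment optima, not BLAST output: there is no
low-complexity masking or composition adjustment, so values will differ
from BLASTx on the same input while preserving the bit-score thresholding
semantics.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from . import ensemble as _ens
from .ensemble import ModelBundle
from .seqio import (
    PROTEIN_ALPHABET,
    NucleotideRecord,
    ProteinRecord,
    six_frame_translate,
)

_AA_INDEX = {a: i for i, a in enumerate(PROTEIN_ALPHABET)}

__all__ = [
    "AlignmentParams",
    "LocalAlignment",
    "ScreenHit",
    "smith_waterman",
    "sw_score",
    "bit_score",
    "screen_contigs",
    "shortlist_candidates",
    "characterize",
    "hits_to_frame",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme and Karlin-Altschul constants for bit conversion.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``. The scan
    used by the aligner requires ``gap_extend <= gap_open``. Defaults are
    the classic gapped-BLOSUM62 values (11/1, lambda=0.267, K=0.041).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")


@functools.lru_cache(maxsize=4)
def _substitution_matrix(name: str) -> np.ndarray:
    """20x20 substitution scores indexed by the standard alphabet order."""
    mat = substitution_matrices.load(name)
    out = np.empty((20, 20))
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            out[i, j] = mat[a, b]
    return out


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from exc


def _dp_rows(
    q: np.ndarray, t: np.ndarray, sub: np.ndarray, open_: float, ext: float,
    keep_matrix: bool,
) -> tuple[float, int, int, np.ndarray | None]:
    """Row-wise affine-gap local DP.

    Vertical gaps carry over from the previous row; horizontal gaps are
    resolved with a prefix-max scan, which is exact when extend <= open
    (re-opening a gap directly after a gap can never beat extending it).
    Returns (best score, best i, best j, full H matrix if requested), where
    the best cell is the first maximum in row-major order.
    """
    n, m = len(q), len(t)
    idx = np.arange(m + 1)
    Hfull = np.zeros(m + 1)
    F = np.full(m, -np.inf)
    best, best_i, best_j = 0.0, 0, 0
    H_all = np.zeros((n + 1, m + 1)) if keep_matrix else None
    for i in range(1, n + 1):
        s = sub[q[i - 1], t]
        F = np.maximum(Hfull[1:] - open_, F - ext)
        diag = Hfull[:-1] + s
        H0 = np.maximum(0.0, np.maximum(diag, F))
        H0full = np.concatenate(([0.0], H0))
        prefix = np.maximum.accumulate(H0full + idx * ext)
        E = prefix[:-1] - open_ - (idx[1:] - 1) * ext
        H = np.maximum(H0, E)
        Hfull = np.concatenate(([0.0], H))
        if keep_matrix:
            H_all[i] = Hfull
        row_best = Hfull.max()
        if row_best > best:
            best = float(row_best)
            best_i = i
            best_j = int(Hfull.argmax())
    return best, best_i, best_j, H_all


def sw_score(query: str, target: str, params: AlignmentParams | None = None) -> float:
    """Optimal local-alignment raw score (score-only fast path)."""
    params = params or AlignmentParams()
    if not query or not target:
        raise ValueError("both sequences must be non-empty")
    sub = _substitution_matrix(params.matrix_name)
    best, _, _, _ = _dp_rows(
        _encode(query), _encode(target), sub, params.gap_open, params.gap_extend, False
    )
    return best


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment: raw score plus 0-based half-open spans."""

    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int


def smith_waterman(
    query: str, target: str, params: AlignmentParams | None = None
) -> LocalAlignment:
    """Exact affine-gap Smith-Waterman with the span of the best-scoring
    local alignment (first-encountered maximum, row-major)."""
    params = params or AlignmentParams()
    if not query or not target:
        raise ValueError("both sequences must be non-empty")
    sub = _substitution_matrix(params.matrix_name)
    q, t = _encode(query), _encode(target)
    open_, ext = params.gap_open, params.gap_extend
    best, i, j, H = _dp_rows(q, t, sub, open_, ext, True)
    end_i, end_j = i, j
    # traceback on H alone: at each cell try diagonal, then vertical and
    # horizontal gaps of every length (scores are exact, so equality holds
    # on the optimal path)
    while i > 0 and j > 0 and H[i, j] > 0:
        if H[i, j] == H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]:
            i -= 1
            j -= 1
            continue
        moved = False
        for L in range(1, i + 1):
            if H[i, j] == H[i - L, j] - open_ - (L - 1) * ext:
                i -= L
                moved = True
                break
        if moved:
            continue
        for L in range(1, j + 1):
            if H[i, j] == H[i, j - L] - open_ - (L - 1) * ext:
                j -= L
                moved = True
                break
        if not moved:  # pragma: no cover - would indicate a DP bug
            raise AssertionError("traceback failed")
    return LocalAlignment(best, i, end_i, j, end_j)


def bit_score(raw_score: float, params: AlignmentParams | None = None) -> float:
    """Karlin-Altschul normalized score: (lambda * S - ln K) / ln 2."""
    params = params or AlignmentParams()
    if not math.isfinite(raw_score):
        raise ValueError("raw score must be finite")
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2)


@dataclass(frozen=True)
class ScreenHit:
    """Best translated-homology hit for one contig."""

    contig_id: str
    frame: int
    peptide: str  # full stop-split peptide containing the alignment
    start: int  # 1-based aa position of the aligned span on the frame
    end: int  # 1-based inclusive
    reference_id: str
    raw_score: float
    bits: float
    align_length: int


def screen_contigs(
    contigs: Sequence[NucleotideRecord],
    references: Sequence[ProteinRecord],
    params: AlignmentParams | None = None,
    cutoff_bits: float = 50.0,
    *,
    min_contig_len: int = 300,
    min_peptide_len: int = 20,
    best_per_contig: bool = True,
) -> list[ScreenHit]:
    """Six-frame translate each contig and align stop-split peptides (>=
    ``min_peptide_len`` aa) against every reference.

    By default only the best-scoring (peptide, reference) pair per contig is
    considered; a hit is emitted iff its bit score reaches ``cutoff_bits``.
    Hits are sorted by descending bit score. Contigs shorter than
    ``min_contig_len`` are skipped.
    """
    params = params or AlignmentParams()
    if not references:
        raise ValueError("reference set is empty")
    hits: list[ScreenHit] = []
    for contig in contigs:
        if len(contig) < min_contig_len:
            continue
        candidates: list[tuple[float, object, object, ProteinRecord]] = []
        best_raw = -np.inf
        best_item = None
        for frame in six_frame_translate(contig):
            for pep in frame.peptides:
                if len(pep.seq) < min_peptide_len:
                    continue
                for ref in references:
                    raw = sw_score(pep.seq, ref.seq, params)
                    if raw > best_raw:
                        best_raw = raw
                        best_item = (frame, pep, ref)
                    if not best_per_contig:
                        candidates.append((raw, frame, pep, ref))
        selected = (
            [(best_raw, *best_item)] if (best_per_contig and best_item) else candidates
        )
        for raw, frame, pep, ref in selected:
            bits = bit_score(raw, params)
            if bits < cutoff_bits:
                continue
            aln = smith_waterman(pep.seq, ref.seq, params)
            hits.append(
                ScreenHit(
                    contig_id=contig.id,
                    frame=frame.frame,
                    peptide=pep.seq,
                    start=pep.aa_start + aln.query_start + 1,
                    end=pep.aa_start + aln.query_end,
                    reference_id=ref.id,
                    raw_score=float(raw),
                    bits=float(bits),
                    align_length=aln.query_end - aln.query_start,
                )
            )
    hits.sort(key=lambda h: (-h.bits, h.contig_id, h.reference_id))
    return hits


def hits_to_frame(hits: Sequence[ScreenHit]) -> pd.DataFrame:
    cols = ["contig_id", "frame", "reference_id", "raw_score", "bits",
            "start", "end", "align_length", "peptide"]
    return pd.DataFrame([{c: getattr(h, c) for c in cols} for h in hits],
                        columns=cols)


def _nearest_rank_threshold(values: Sequence[float], quantile: float) -> float:
    """Smallest value with at least ``quantile`` of the data strictly below
    it (rank floor(q*n)+1 of the ascending order statistics, capped at n).

    With q = 0.75 and n divisible by 4 this keeps exactly the top 25%.
    """
    ordered = sorted(values)
    n = len(ordered)
    rank = min(int(math.floor(quantile * n)) + 1, n)
    return ordered[rank - 1]


def shortlist_candidates(
    hits: Sequence[ScreenHit],
    coverage: Mapping[str, float],
    bit_floor: float = 300.0,
    coverage_quantile: float = 0.75,
) -> pd.DataFrame:
    """Candidate table: per hit contig its best hit, coverage and a
    shortlist flag (coverage at or above the nearest-rank quantile of all
    supplied coverages AND bit score >= ``bit_floor``)."""
    missing = sorted({h.contig_id for h in hits} - set(coverage))
    if missing:
        raise ValueError(f"hit contigs without coverage entries: {missing}")
    rows = []
    threshold = (
        _nearest_rank_threshold(list(coverage.values()), coverage_quantile)
        if coverage
        else float("inf")
    )
    for h in hits:
        cov = float(coverage[h.contig_id])
        rows.append(
            {
                "contig_id": h.contig_id,
                "reference_id": h.reference_id,
                "bits": h.bits,
                "coverage": cov,
                "shortlisted": bool(cov >= threshold and h.bits >= bit_floor),
            }
        )
    return pd.DataFrame(
        rows, columns=["contig_id", "reference_id", "bits", "coverage", "shortlisted"]
    )


def characterize(
    contigs: Sequence[NucleotideRecord],
    references: Sequence[ProteinRecord],
    bundle_t: ModelBundle | None,
    bundle_ph: ModelBundle | None,
    params: AlignmentParams | None = None,
    cutoff_bits: float = 50.0,
    **screen_kwargs,
) -> pd.DataFrame:
    """Screen contigs, then classify each passing peptide with the
    temperature and/or pH bundles.

    Peptides too short for a bundle's descriptors are marked
    ``unpredictable`` rather than failing the run.
    """
    hits = screen_contigs(contigs, references, params, cutoff_bits, **screen_kwargs)
    rows = []
    predictions: dict[str, dict] = {}
    for task, bundle in (("t", bundle_t), ("ph", bundle_ph)):
        if bundle is None:
            continue
        records = [ProteinRecord(h.contig_id, h.peptide) for h in hits]
        if records:
            for res in _ens.predict(bundle, records):
                predictions.setdefault(res.id, {})[task] = res
    for h in hits:
        row: dict = {
            "contig_id": h.contig_id,
            "reference_id": h.reference_id,
            "frame": h.frame,
            "bits": h.bits,
            "peptide": h.peptide,
        }
        for task, prefix, bundle in (
            ("t", "temperature", bundle_t), ("ph", "ph", bundle_ph)
        ):
            if bundle is None:
                continue
            res = predictions.get(h.contig_id, {}).get(task)
            if res is None or res.error:
                row[f"{prefix}_label"] = "unpredictable"
            else:
                row[f"{prefix}_label"] = res.label
                for cls, p in res.probabilities.items():
                    row[f"{prefix}_p_{cls}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
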