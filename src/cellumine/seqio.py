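"""Sequence I/O and preprocessing.

FASTA reading/writing, amino-acid sequence cleaning, six-frame translation
of nucleotide contigs, and greedy identity-based redundancy clustering of
protein sets.

Coordinates are 0-based and half-open internally; user-facing reports are
1-based.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_SET = frozenset(PROTEIN_ALPHABET)
_NUC_SET = frozenset("ACGTN")
# IUPAC ambiguity letters collapsed to N on read
_NUC_AMBIGUOUS = frozenset("RYSWKMBDHVN")

__all__ = [
    "PROTEIN_ALPHABET",
    "ProteinRecord",
    "NucleotideRecord",
    "PeptideSegment",
    "TranslatedFrame",
    "Cluster",
    "read_fasta",
    "write_fasta",
    "clean_sequence",
    "six_frame_translate",
    "greedy_cluster",
    "greedy_cluster_detailed",
    "pairwise_identity",
    "write_cluster_report",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence over the 20 standard residues."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.seq) - _PROTEIN_SET
        if bad:
            raise ValueError(
                f"protein record {self.id!r} contains non-standard characters "
                f"{sorted(bad)}; run clean_sequence first"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class NucleotideRecord:
    """A named DNA sequence over {A, C, G, T, N}, uppercase canonical form."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"nucleotide record {self.id!r} has an empty sequence")
        bad = set(self.seq) - _NUC_SET
        if bad:
            raise ValueError(
                f"nucleotide record {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucleotideRecord":
        return NucleotideRecord(self.id, str(Seq(self.seq).reverse_complement()))


@dataclass(frozen=True)
class PeptideSegment:
    """A stop-free translated segment within one reading frame.

    ``aa_start`` is the 0-based index of the first residue in the frame's
    full translation; ``nt_start`` is the 0-based nucleotide offset of its
    first codon on the strand being translated (forward contig for ``+``
    frames, reverse complement for ``-`` frames).
    """

    seq: str
    aa_start: int
    nt_start: int


@dataclass(frozen=True)
class TranslatedFrame:
    contig_id: str
    frame: int  # one of +1, +2, +3, -1, -2, -3
    peptides: tuple[PeptideSegment, ...]


def clean_sequence(raw: str) -> str:
    """Uppercase ``raw`` and strip every character outside the 20-letter
    amino-acid alphabet (ambiguity codes B/J/O/U/X/Z, gaps, stops, digits...).

    Raises ``ValueError`` when nothing remains.
    """
    cleaned = "".join(c for c in raw.upper() if c in _PROTEIN_SET)
    if not cleaned:
        raise ValueError("sequence is empty after cleaning")
    return cleaned


def _normalize_nucleotide(raw: str, record_id: str) -> str:
    out = []
    for c in raw.upper():
        if c in "ACGT":
            out.append(c)
        elif c in _NUC_AMBIGUOUS:
            out.append("N")
        else:
            raise ValueError(
                f"nucleotide record {record_id!r} contains invalid character {c!r}"
            )
    return "".join(out)


def read_fasta(
    path: str | Path,
    alphabet: Literal["protein", "nucleotide"] = "protein",
    *,
    clean: bool = False,
) -> list[ProteinRecord] | list[NucleotideRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased and order is preserved. With
    ``alphabet="protein"`` and ``clean=True`` non-standard characters are
    stripped (see :func:`clean_sequence`); without ``clean`` they raise.
    Ambiguous nucleotide codes are collapsed to ``N``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} in {path} has an empty sequence")
        if alphabet == "protein":
            if clean:
                try:
                    seq = clean_sequence(seq)
                except ValueError as exc:
                    raise ValueError(f"record {rec.id!r}: {exc}") from exc
            records.append(ProteinRecord(rec.id, seq))
        elif alphabet == "nucleotide":
            records.append(NucleotideRecord(rec.id, _normalize_nucleotide(seq, rec.id)))
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown alphabet {alphabet!r}")
    if not records:
        raise ValueError(f"FASTA file {path} contains no records")
    return records


def write_fasta(
    records: Iterable[ProteinRecord | NucleotideRecord],
    path: str | Path,
    width: int = 60,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=4)
def _codon_maps(table_id: int) -> tuple[dict, frozenset]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


def _translate_frame(strand_seq: str, offset: int, table_id: int) -> list[PeptideSegment]:
    forward, stops = _codon_maps(table_id)
    peptides: list[PeptideSegment] = []
    chunk: list[str] = []
    chunk_aa_start = 0
    aa_index = 0
    for nt in range(offset, len(strand_seq) - 2, 3):
        codon = strand_seq[nt : nt + 3]
        aa = None if (codon in stops or "N" in codon) else forward.get(codon)
        if aa is None:
            # stop codon or ambiguous codon: break the segment
            if chunk:
                peptides.append(
                    PeptideSegment(
                        "".join(chunk), chunk_aa_start, offset + 3 * chunk_aa_start
                    )
                )
                chunk = []
        else:
            if not chunk:
                chunk_aa_start = aa_index
            chunk.append(aa)
        aa_index += 1
    if chunk:
        peptides.append(
            PeptideSegment("".join(chunk), chunk_aa_start, offset + 3 * chunk_aa_start)
        )
    return peptides


def six_frame_translate(
    contig: NucleotideRecord, table_id: int = 1
) -> list[TranslatedFrame]:
    """Translate a contig in all six frames with the standard genetic code.

    Each frame's translation is split at stop codons into stop-free
    peptides; codons containing ``N`` also break segments. Frames are
    returned in the order +1, +2, +3, -1, -2, -3. Contigs shorter than 3 nt
    yield six empty frames.
    """
    frames: list[TranslatedFrame] = []
    rc = str(Seq(contig.seq).reverse_complement())
    for strand, strand_seq in ((1, contig.seq), (-1, rc)):
        for offset in range(3):
            peptides = (
                _translate_frame(strand_seq, offset, table_id)
                if len(contig) >= 3
                else []
            )
            frames.append(
                TranslatedFrame(contig.id, strand * (offset + 1), tuple(peptides))
            )
    return frames


# ---------------------------------------------------------------------------
# Greedy identity clustering
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _identity_aligner() -> PairwiseAligner:
    # Global alignment maximizing matches: match +1, mismatch 0, gap -1.
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions in the optimal global alignment,
    normalized by the shorter sequence's length."""
    aln = _identity_aligner().align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


@dataclass
class Cluster:
    representative: ProteinRecord
    members: list[tuple[ProteinRecord, float]] = field(default_factory=list)


def greedy_cluster_detailed(
    records: Sequence[ProteinRecord], identity_threshold: float = 0.9
) -> list[Cluster]:
    """Greedy incremental clustering in descending-length order.

    Each record joins the first existing cluster whose representative it
    matches at >= ``identity_threshold`` identity, otherwise founds a new
    cluster. Because records are processed longest-first, the founder is the
    longest member and serves as representative.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: -len(r.seq))  # stable: ties keep input order
    clusters: list[Cluster] = []
    for rec in ordered:
        placed = False
        for cluster in clusters:
            ident = pairwise_identity(rec.seq, cluster.representative.seq)
            if ident >= identity_threshold:
                cluster.members.append((rec, ident))
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec, [(rec, 1.0)]))
    return clusters


def greedy_cluster(
    records: Sequence[ProteinRecord], identity_threshold: float = 0.9
) -> list[ProteinRecord]:
    """Representatives (longest member per cluster) of greedy clustering."""
    return [c.representative for c in greedy_cluster_detailed(records, identity_threshold)]


def write_cluster_report(clusters: Sequence[Cluster], path: str | Path) -> None:
    """TSV report: representative_id, member_id, identity."""
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_id\tidentity\n")
        for cluster in clusters:
            for member, ident in cluster.members:
                fh.write(f"{cluster.representative.id}\t{member.id}\t{ident:.4f}\n")
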