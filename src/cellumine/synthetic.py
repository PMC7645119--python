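"""Seeded synthetic data: labeled protein sets with class-conditional
residue-composition biases, and DNA contigs with planted (forward or
reverse-strand) reference-like genes inside random background sequence.

The signal mechanism is a multiplicative residue-weight bias per class
(thermostable classes enriched in I/V/Y/W/R/E/L, acidic in D/E, alkaline in
K/R); a strength parameter scales the bias so both null (strength 0) and
high-power fixtures exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .labeling import LabeledDataset, OptimaRecord, label_ph, label_temperature
from .seqio import PROTEIN_ALPHABET, NucleotideRecord, ProteinRecord

__all__ = [
    "ClassSpec",
    "ContigSpec",
    "sample_protein",
    "generate_labeled_dataset",
    "temperature_class_specs",
    "ph_class_specs",
    "reverse_translate",
    "generate_contigs",
    "generate_reference_set",
]

THERMO_ENRICHED = "IVYWREL"
ACIDIC_ENRICHED = "DE"
ALKALINE_ENRICHED = "KR"


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic class: sample count, length range, residue bias and the
    optimum-value range to assign (must lie inside the class interval)."""

    name: str
    n: int
    length_range: tuple[int, int]
    bias: Mapping[str, float]
    optimum_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(w <= 0 for w in self.bias.values()):
            raise ValueError("bias weights must be positive")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length range")


def _weights(bias: Mapping[str, float]) -> np.ndarray:
    w = np.array([bias.get(a, 1.0) for a in PROTEIN_ALPHABET], dtype=float)
    if np.any(w <= 0):
        raise ValueError("bias weights must be positive")
    return w / w.sum()


def sample_protein(length: int, bias: Mapping[str, float], rng: np.random.Generator) -> str:
    """Draw ``length`` i.i.d. residues from the normalized weight distribution."""
    if length < 1:
        raise ValueError("length must be >= 1")
    probs = _weights(bias)
    letters = rng.choice(list(PROTEIN_ALPHABET), size=length, p=probs)
    return "".join(letters)


def _enrichment(residues: str, factor: float) -> dict[str, float]:
    return {a: factor for a in residues}


def temperature_class_specs(
    n_per_class: int = 60,
    strength: float = 1.0,
    length_range: tuple[int, int] = (120, 220),
) -> list[ClassSpec]:
    """Default 3-class temperature fixture; strength 0 removes the signal.

    Optimum ranges sit strictly inside the class intervals so labels are
    unambiguous.
    """
    return [
        ClassSpec("mesophilic", n_per_class, length_range, {}, (25.0, 45.0)),
        ClassSpec(
            "thermophilic", n_per_class, length_range,
            _enrichment(THERMO_ENRICHED, 1.0 + strength), (55.0, 70.0),
        ),
        ClassSpec(
            "hyperthermophilic", n_per_class, length_range,
            _enrichment(THERMO_ENRICHED, 1.0 + 2.5 * strength), (80.0, 105.0),
        ),
    ]


def ph_class_specs(
    n_per_class: int = 60,
    strength: float = 1.0,
    length_range: tuple[int, int] = (120, 220),
) -> list[ClassSpec]:
    return [
        ClassSpec(
            "acidic", n_per_class, length_range,
            _enrichment(ACIDIC_ENRICHED, 1.0 + 2.0 * strength), (3.0, 4.5),
        ),
        ClassSpec("neutral", n_per_class, length_range, {}, (5.5, 7.5)),
        ClassSpec(
            "alkaline", n_per_class, length_range,
            _enrichment(ALKALINE_ENRICHED, 1.0 + 2.0 * strength), (8.5, 11.0),
        ),
    ]


def generate_labeled_dataset(
    specs: Sequence[ClassSpec], task: str, seed: int = 0
) -> LabeledDataset:
    """Draw each class's sequences and optima; the recomputed threshold
    label of every assigned optimum must equal the generating class."""
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    optima: dict[str, OptimaRecord] = {}
    label_fn = label_temperature if task == "temperature" else label_ph
    for spec in specs:
        for i in range(spec.n):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            seq = sample_protein(length, spec.bias, rng)
            value = float(rng.uniform(*spec.optimum_range))
            if label_fn(value) != spec.name:
                raise ValueError(
                    f"optimum range of class {spec.name!r} leaves its interval: "
                    f"{value} labels as {label_fn(value)!r}"
                )
            rec_id = f"{task}_{spec.name}_{i + 1:03d}"
            records.append(ProteinRecord(rec_id, seq))
            optima[rec_id] = OptimaRecord(
                rec_id,
                t_opt=value if task == "temperature" else None,
                ph_opt=value if task == "ph" else None,
            )
    return LabeledDataset(records, optima)


@dataclass(frozen=True)
class ContigSpec:
    """Synthetic contig set: counts, length range and planting fractions."""

    n_contigs: int = 20
    length_range: tuple[int, int] = (5000, 10000)
    planted_fraction: float = 0.6
    reverse_strand_fraction: float = 1 / 3  # of the planted contigs

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0 <= self.reverse_strand_fraction <= 1:
            raise ValueError("reverse_strand_fraction must be in [0, 1]")


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(_aa, []).append(_codon)
_STOP_CODONS = sorted(CodonTable.unambiguous_dna_by_id[1].stop_codons)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Pick a synonymous codon uniformly per residue and append a stop."""
    codons = [
        str(rng.choice(sorted(_BACK_TABLE[aa]))) for aa in protein
    ]
    codons.append(str(rng.choice(_STOP_CODONS)))
    return "".join(codons)


def _reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def generate_contigs(
    spec: ContigSpec,
    reference_proteins: Sequence[ProteinRecord],
    seed: int = 0,
) -> tuple[list[NucleotideRecord], pd.DataFrame]:
    """Random-background contigs, a subset carrying a reverse-translated
    reference gene (some reverse-complemented), plus a truth table with
    columns contig_id, reference_id, strand, offset."""
    if not reference_proteins:
        raise ValueError("need at least one reference protein")
    rng = np.random.default_rng(seed)
    n_planted = round(spec.planted_fraction * spec.n_contigs)
    n_reverse = round(spec.reverse_strand_fraction * n_planted)
    planted_flags = np.zeros(spec.n_contigs, dtype=bool)
    planted_flags[:n_planted] = True
    rng.shuffle(planted_flags)
    reverse_flags = np.zeros(n_planted, dtype=bool)
    reverse_flags[:n_reverse] = True
    rng.shuffle(reverse_flags)
    contigs: list[NucleotideRecord] = []
    truth_rows: list[dict] = []
    planted_seen = 0
    for i in range(spec.n_contigs):
        contig_id = f"contig_{i + 1:03d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        if planted_flags[i]:
            ref = reference_proteins[int(rng.integers(len(reference_proteins)))]
            gene = reverse_translate(ref.seq, rng)
            if len(gene) + 200 > length:
                raise ValueError(
                    f"reference {ref.id!r} gene ({len(gene)} nt) too long for "
                    f"contig length {length} (needs gene + 200)"
                )
            strand = "-" if reverse_flags[planted_seen] else "+"
            planted_seen += 1
            insert = gene if strand == "+" else _reverse_complement(gene)
            offset = int(rng.integers(100, length - len(gene) - 100 + 1))
            background = _random_dna(length, rng)
            seq = background[:offset] + insert + background[offset + len(insert):]
            truth_rows.append(
                {"contig_id": contig_id, "reference_id": ref.id, "strand": strand,
                 "offset": offset}
            )
        else:
            seq = _random_dna(length, rng)
            truth_rows.append(
                {"contig_id": contig_id, "reference_id": "none", "strand": "",
                 "offset": -1}
            )
        contigs.append(NucleotideRecord(contig_id, seq))
    truth = pd.DataFrame(
        truth_rows, columns=["contig_id", "reference_id", "strand", "offset"]
    )
    return contigs, truth


def generate_reference_set(
    n: int = 15,
    length_range: tuple[int, int] = (120, 260),
    bias: Mapping[str, float] | None = None,
    seed: int = 0,
    prefix: str = "ref",
) -> list[ProteinRecord]:
    """Random reference proteins standing in for a curated enzyme set."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(
            ProteinRecord(f"{prefix}_{i + 1:03d}", sample_protein(length, bias or {}, rng))
        )
    return out
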