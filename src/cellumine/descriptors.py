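"""Length-independent numeric descriptors for protein sequences.

Each descriptor block maps a cleaned amino-acid sequence to a fixed-order
vector; :func:`featurize` concatenates the enabled blocks into a
:class:`FeatureMatrix`. The default block set (AAC, DPC, grouped AAC/DPC,
CTD composition/transition/distribution, conjoint triad, pseudo-AAC with
lambda=4, atom and bond composition) yields 973 uniquely named columns.

Composition blocks sum to 1 per sequence. All group partitions and
physico-chemical scales are embedded as documented constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import PROTEIN_ALPHABET, ProteinRecord

AA = PROTEIN_ALPHABET
_AA_INDEX = {a: i for i, a in enumerate(AA)}

__all__ = [
    "DescriptorConfig",
    "FeatureMatrix",
    "ScalerState",
    "aac",
    "dpc",
    "gaac",
    "gdpc",
    "ctdc",
    "ctdt",
    "ctdd",
    "conjoint_triad",
    "paac",
    "atom_bond",
    "featurize",
    "drop_duplicate_columns",
    "fit_scaler",
    "apply_scaler",
    "project_columns",
    "BLOCKS",
]

# ---------------------------------------------------------------------------
# Embedded constant tables
# ---------------------------------------------------------------------------

# Five-way physicochemical grouping used for grouped AAC/DPC.
GAAC_GROUPS: tuple[tuple[str, str], ...] = (
    ("aliphatic", "GAVLMI"),
    ("aromatic", "FYW"),
    ("positive", "KRH"),
    ("negative", "DE"),
    ("uncharged", "STCPNQ"),
)

# Classic 7-attribute, 3-group CTD partitions of the amino-acid alphabet.
CTD_ATTRIBUTES: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("hydrophobicity", ("RKEDQN", "GASTPHY", "CLVIMFW")),
    ("vdw_volume", ("GASCTPD", "NVEQIL", "MHKFRYW")),
    ("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    ("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    ("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    ("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    ("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MSPTHY")),
)

# Conjoint-triad 7-class partition (dipole/side-chain-volume based).
CT_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

# Pseudo-AAC property scales: hydrophobicity, hydrophilicity, side-chain mass.
_PAAC_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_PAAC_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_PAAC_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}

# Atoms (C, H, N, O, S) of the free amino acid, from molecular formulas.
ATOM_COUNTS: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 7, 1, 2, 0), "R": (6, 14, 4, 2, 0), "N": (4, 8, 2, 3, 0),
    "D": (4, 7, 1, 4, 0), "C": (3, 7, 1, 2, 1), "E": (5, 9, 1, 4, 0),
    "Q": (5, 10, 2, 3, 0), "G": (2, 5, 1, 2, 0), "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0), "L": (6, 13, 1, 2, 0), "K": (6, 14, 2, 2, 0),
    "M": (5, 11, 1, 2, 1), "F": (9, 11, 1, 2, 0), "P": (5, 9, 1, 2, 0),
    "S": (3, 7, 1, 3, 0), "T": (4, 9, 1, 3, 0), "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0), "V": (5, 11, 1, 2, 0),
}

# Bonds of the free amino-acid molecular graph: (total edges, single bonds,
# localized double bonds, aromatic rings). Aromatic ring edges are counted in
# the total but in neither the single nor the double tally.
BOND_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "G": (9, 8, 1, 0), "A": (12, 11, 1, 0), "V": (18, 17, 1, 0),
    "L": (21, 20, 1, 0), "I": (21, 20, 1, 0), "P": (17, 16, 1, 0),
    "F": (23, 16, 1, 1), "W": (28, 17, 1, 2), "M": (19, 18, 1, 0),
    "S": (13, 12, 1, 0), "T": (16, 15, 1, 0), "C": (13, 12, 1, 0),
    "Y": (24, 17, 1, 1), "N": (16, 14, 2, 0), "Q": (19, 17, 2, 0),
    "D": (15, 13, 2, 0), "E": (18, 16, 2, 0), "K": (23, 22, 1, 0),
    "R": (25, 23, 2, 0), "H": (20, 14, 1, 1),
}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from exc


def _require_length(seq: str, minimum: int, block: str) -> None:
    if len(seq) < minimum:
        raise ValueError(
            f"sequence of length {len(seq)} is too short for {block} "
            f"(needs >= {minimum})"
        )


# ---------------------------------------------------------------------------
# Descriptor blocks
# ---------------------------------------------------------------------------

def aac(seq: str) -> np.ndarray:
    """Amino-acid composition: per-residue frequency, 20 values."""
    _require_length(seq, 1, "AAC")
    counts = np.bincount(_encode(seq), minlength=20)
    return counts / len(seq)


def dpc(seq: str) -> np.ndarray:
    """Dipeptide composition: ordered pair frequency, 400 values."""
    _require_length(seq, 2, "DPC")
    idx = _encode(seq)
    pairs = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pairs, minlength=400)
    return counts / (len(seq) - 1)


_GAAC_MAP = np.empty(20, dtype=np.int64)
for _gi, (_, _members) in enumerate(GAAC_GROUPS):
    for _c in _members:
        _GAAC_MAP[_AA_INDEX[_c]] = _gi


def gaac(seq: str) -> np.ndarray:
    """Grouped amino-acid composition over 5 physicochemical groups."""
    _require_length(seq, 1, "GAAC")
    counts = np.bincount(_GAAC_MAP[_encode(seq)], minlength=5)
    return counts / len(seq)


def gdpc(seq: str) -> np.ndarray:
    """Grouped dipeptide composition, 25 values."""
    _require_length(seq, 2, "GDPC")
    idx = _GAAC_MAP[_encode(seq)]
    pairs = idx[:-1] * 5 + idx[1:]
    counts = np.bincount(pairs, minlength=25)
    return counts / (len(seq) - 1)


_CTD_MAPS: list[np.ndarray] = []
for _, _groups in CTD_ATTRIBUTES:
    _m = np.empty(20, dtype=np.int64)
    for _gi, _members in enumerate(_groups):
        for _c in _members:
            _m[_AA_INDEX[_c]] = _gi
    _CTD_MAPS.append(_m)


def ctdc(seq: str) -> np.ndarray:
    """CTD composition: group frequency per attribute, 7 x 3 values."""
    _require_length(seq, 2, "CTDC")
    idx = _encode(seq)
    out = np.empty(21)
    for a, mapping in enumerate(_CTD_MAPS):
        out[3 * a : 3 * a + 3] = np.bincount(mapping[idx], minlength=3) / len(seq)
    return out


def ctdt(seq: str) -> np.ndarray:
    """CTD transition: adjacent-pair group-change frequency per unordered
    group pair (g1g2, g1g3, g2g3), normalized by length - 1."""
    _require_length(seq, 2, "CTDT")
    idx = _encode(seq)
    out = np.empty(21)
    denom = len(seq) - 1
    for a, mapping in enumerate(_CTD_MAPS):
        g = mapping[idx]
        left, right = g[:-1], g[1:]
        lo = np.minimum(left, right)
        hi = np.maximum(left, right)
        out[3 * a + 0] = np.count_nonzero((lo == 0) & (hi == 1)) / denom
        out[3 * a + 1] = np.count_nonzero((lo == 0) & (hi == 2)) / denom
        out[3 * a + 2] = np.count_nonzero((lo == 1) & (hi == 2)) / denom
    return out


_CTDD_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.0)


def ctdd(seq: str) -> np.ndarray:
    """CTD distribution: percent position of the 1st, 25%, 50%, 75% and
    100% occurrence of each group (0 for absent groups), 7 x 3 x 5 values."""
    _require_length(seq, 2, "CTDD")
    idx = _encode(seq)
    L = len(seq)
    out = np.zeros(105)
    pos = np.arange(1, L + 1)  # 1-based positions
    for a, mapping in enumerate(_CTD_MAPS):
        g = mapping[idx]
        for gi in range(3):
            where = pos[g == gi]
            base = a * 15 + gi * 5
            if where.size == 0:
                continue
            m = where.size
            for fi, frac in enumerate(_CTDD_FRACTIONS):
                occurrence = max(1, int(np.ceil(frac * m)))
                out[base + fi] = where[occurrence - 1] / L * 100.0
    return out


_CT_MAP = np.empty(20, dtype=np.int64)
for _gi, _members in enumerate(CT_CLASSES):
    for _c in _members:
        _CT_MAP[_AA_INDEX[_c]] = _gi


def conjoint_triad(seq: str) -> np.ndarray:
    """Conjoint-triad: frequency of ordered 7-class triples, 343 values."""
    _require_length(seq, 3, "conjoint triad")
    idx = _CT_MAP[_encode(seq)]
    triples = idx[:-2] * 49 + idx[1:-1] * 7 + idx[2:]
    counts = np.bincount(triples, minlength=343)
    return counts / (len(seq) - 2)


def _normalized_scale(table: Mapping[str, float]) -> np.ndarray:
    vals = np.array([table[a] for a in AA])
    return (vals - vals.mean()) / vals.std()  # population std over the 20 residues


_PAAC_SCALES = np.stack(
    [
        _normalized_scale(_PAAC_HYDROPHOBICITY),
        _normalized_scale(_PAAC_HYDROPHILICITY),
        _normalized_scale(_PAAC_SIDECHAIN_MASS),
    ]
)


def paac(seq: str, lam: int = 4, w: float = 0.05) -> np.ndarray:
    """Type-1 pseudo amino-acid composition: 20 + lam values.

    First 20 entries are f_i / (1 + w * sum(theta)); the last ``lam`` are
    w * theta_k / (1 + w * sum(theta)) with theta_k the mean squared
    normalized-property difference at sequence separation k.
    """
    if lam < 1:
        raise ValueError("lam must be >= 1")
    if len(seq) <= lam:
        raise ValueError(
            f"sequence of length {len(seq)} is too short for PAAC with lam={lam}; "
            "drop the PAAC block for this set or lower lam"
        )
    idx = _encode(seq)
    props = _PAAC_SCALES[:, idx]  # (3, L)
    theta = np.empty(lam)
    for k in range(1, lam + 1):
        diffs = props[:, :-k] - props[:, k:]
        theta[k - 1] = np.mean(diffs**2, axis=0).mean()
    freqs = np.bincount(idx, minlength=20) / len(seq)
    denom = 1.0 + w * theta.sum()
    return np.concatenate([freqs / denom, w * theta / denom])


_ATOM_TABLE = np.array([ATOM_COUNTS[a] for a in AA], dtype=float)
_BOND_TABLE = np.array([BOND_COUNTS[a] for a in AA], dtype=float)


def atom_bond(seq: str) -> np.ndarray:
    """Atom composition (C, H, N, O, S fractions of total atoms) and
    per-residue bond averages (total, single, double, aromatic rings)."""
    _require_length(seq, 1, "atom/bond composition")
    idx = _encode(seq)
    atoms = _ATOM_TABLE[idx].sum(axis=0)
    bonds = _BOND_TABLE[idx].sum(axis=0)
    return np.concatenate([atoms / atoms.sum(), bonds / len(seq)])


# ---------------------------------------------------------------------------
# Block registry and featurize
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Block:
    fn: Callable[..., np.ndarray]
    names: Callable[["DescriptorConfig"], list[str]]
    min_length: Callable[["DescriptorConfig"], int]
    composition: bool  # block sums to 1 per sequence


def _pair_names(prefix: str, symbols: Sequence[str]) -> list[str]:
    return [f"{prefix}_{a}{b}" for a in symbols for b in symbols]


def _ctd_names(kind: str) -> list[str]:
    names = []
    for attr, _ in CTD_ATTRIBUTES:
        if kind == "D":
            for gi in range(1, 4):
                for frac in ("first", "p25", "p50", "p75", "p100"):
                    names.append(f"CTDD_{attr}_g{gi}_{frac}")
        elif kind == "C":
            names.extend(f"CTDC_{attr}_g{gi}" for gi in range(1, 4))
        else:
            names.extend(f"CTDT_{attr}_{p}" for p in ("g1g2", "g1g3", "g2g3"))
    return names


_GROUP_NAMES = [name for name, _ in GAAC_GROUPS]

BLOCKS: dict[str, _Block] = {
    "aac": _Block(lambda s, c: aac(s), lambda c: [f"AAC_{a}" for a in AA],
                  lambda c: 1, True),
    "dpc": _Block(lambda s, c: dpc(s), lambda c: _pair_names("DPC", list(AA)),
                  lambda c: 2, True),
    "gaac": _Block(lambda s, c: gaac(s), lambda c: [f"GAAC_{g}" for g in _GROUP_NAMES],
                   lambda c: 1, True),
    "gdpc": _Block(lambda s, c: gdpc(s), lambda c: _pair_names("GDPC", _GROUP_NAMES),
                   lambda c: 2, True),
    "ctdc": _Block(lambda s, c: ctdc(s), lambda c: _ctd_names("C"), lambda c: 2, False),
    "ctdt": _Block(lambda s, c: ctdt(s), lambda c: _ctd_names("T"), lambda c: 2, False),
    "ctdd": _Block(lambda s, c: ctdd(s), lambda c: _ctd_names("D"), lambda c: 2, False),
    "ct": _Block(
        lambda s, c: conjoint_triad(s),
        lambda c: [f"CT_{i}{j}{k}" for i in range(1, 8) for j in range(1, 8)
                   for k in range(1, 8)],
        lambda c: 3, True),
    "paac": _Block(
        lambda s, c: paac(s, c.paac_lam, c.paac_w),
        lambda c: [f"PAAC_{a}" for a in AA]
        + [f"PAAC_theta{k}" for k in range(1, c.paac_lam + 1)],
        lambda c: c.paac_lam + 1, False),
    "atom_bond": _Block(
        lambda s, c: atom_bond(s),
        lambda c: [f"ATOM_{e}" for e in "CHNOS"]
        + ["BOND_total", "BOND_single", "BOND_double", "BOND_aromatic_rings"],
        lambda c: 1, False),
}

DEFAULT_BLOCK_ORDER = tuple(BLOCKS)


@dataclass(frozen=True)
class DescriptorConfig:
    """Which blocks to compute, in fixed registry order, plus PAAC params."""

    blocks: tuple[str, ...] = DEFAULT_BLOCK_ORDER
    paac_lam: int = 4
    paac_w: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.blocks) - set(BLOCKS)
        if unknown:
            raise ValueError(f"unknown descriptor blocks: {sorted(unknown)}")
        if len(set(self.blocks)) != len(self.blocks):
            raise ValueError("duplicate blocks in config")
        if self.paac_lam < 1:
            raise ValueError("paac_lam must be >= 1")
        if self.paac_w < 0:
            raise ValueError("paac_w must be non-negative")

    def column_names(self) -> list[str]:
        names: list[str] = []
        for block in self.blocks:
            names.extend(BLOCKS[block].names(self))
        return names

    def min_sequence_length(self) -> int:
        return max(BLOCKS[b].min_length(self) for b in self.blocks)

    def to_dict(self) -> dict:
        return {"blocks": list(self.blocks), "paac_lam": self.paac_lam,
                "paac_w": self.paac_w}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DescriptorConfig":
        return cls(tuple(d["blocks"]), int(d["paac_lam"]), float(d["paac_w"]))


@dataclass
class FeatureMatrix:
    """Rows = sequences, columns = named descriptors, plus a provenance log
    of applied transforms (dedup, scaling, selection, projection)."""

    ids: list[str]
    columns: list[str]
    data: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-dimensional")
        if self.data.shape != (len(self.ids), len(self.columns)):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.ids)} ids x {len(self.columns)} columns"
            )
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def take_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            [self.ids[i] for i in idx], list(self.columns),
            self.data[idx].copy(), list(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=pd.Index(self.ids, name="id"),
                            columns=self.columns)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")
        sidecar = Path(str(path) + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = Path(str(path) + ".provenance.json")
        provenance = json.loads(sidecar.read_text()) if sidecar.exists() else []
        return cls(list(frame.index.astype(str)), list(frame.columns),
                   frame.to_numpy(), provenance)


def featurize(
    records: Sequence[ProteinRecord], config: DescriptorConfig | None = None
) -> FeatureMatrix:
    """Compute the configured descriptor blocks for every record.

    All sequences must satisfy the strictest per-block length precondition;
    offenders are reported together in one error.
    """
    config = config or DescriptorConfig()
    min_len = config.min_sequence_length()
    offenders = [r.id for r in records if len(r.seq) < min_len]
    if offenders:
        raise ValueError(
            f"sequences too short (< {min_len} residues) for the configured "
            f"descriptor blocks: {offenders}"
        )
    columns = config.column_names()
    data = np.empty((len(records), len(columns)))
    for i, rec in enumerate(records):
        parts = [BLOCKS[b].fn(rec.seq, config) for b in config.blocks]
        data[i] = np.concatenate(parts) if parts else np.empty(0)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite descriptor values produced")
    return FeatureMatrix([r.id for r in records], columns, data,
                         [{"op": "featurize", "config": config.to_dict()}])


def drop_duplicate_columns(m: FeatureMatrix) -> FeatureMatrix:
    """Remove columns whose value vectors exactly equal an earlier column's,
    keeping the first occurrence."""
    if m.shape[0] < 1:
        raise ValueError("need at least one row to detect duplicate columns")
    seen: dict[bytes, str] = {}
    keep: list[int] = []
    dropped: list[str] = []
    for j, name in enumerate(m.columns):
        key = m.data[:, j].tobytes()
        if key in seen:
            dropped.append(name)
        else:
            seen[key] = name
            keep.append(j)
    return FeatureMatrix(
        list(m.ids), [m.columns[j] for j in keep], m.data[:, keep].copy(),
        m.provenance + [{"op": "drop_duplicate_columns", "dropped": dropped}],
    )


def project_columns(m: FeatureMatrix, columns: Sequence[str]) -> FeatureMatrix:
    """Reorder/subset ``m`` to exactly ``columns`` (training column set)."""
    index = {name: j for j, name in enumerate(m.columns)}
    missing = [c for c in columns if c not in index]
    if missing:
        raise ValueError(f"matrix lacks required columns: {missing[:5]}...")
    sel = [index[c] for c in columns]
    return FeatureMatrix(
        list(m.ids), list(columns), m.data[:, sel].copy(),
        m.provenance + [{"op": "project", "n_columns": len(columns)}],
    )


@dataclass
class ScalerState:
    """Per-column min/max learned from a training matrix."""

    columns: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def to_dict(self) -> dict:
        return {"columns": self.columns, "mins": self.mins.tolist(),
                "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScalerState":
        return cls(list(d["columns"]), np.asarray(d["mins"], dtype=float),
                   np.asarray(d["maxs"], dtype=float))


def fit_scaler(train: FeatureMatrix) -> ScalerState:
    """Learn per-column min and max for 0-1 rescaling (>= 2 rows)."""
    if train.shape[0] < 2:
        raise ValueError("scaler requires at least 2 training rows")
    return ScalerState(list(train.columns), train.data.min(axis=0),
                       train.data.max(axis=0))


def apply_scaler(state: ScalerState, m: FeatureMatrix) -> FeatureMatrix:
    """Map x to (x - min) / (max - min) per column; constant training columns
    map to 0. Values outside the training range are not clipped."""
    if state is None or state.mins is None:
        raise ValueError("scaler state is not fitted")
    if list(m.columns) != state.columns:
        raise ValueError("column names do not match the fitted scaler")
    span = state.maxs - state.mins
    out = np.zeros_like(m.data)
    nonconst = span > 0
    out[:, nonconst] = (m.data[:, nonconst] - state.mins[nonconst]) / span[nonconst]
    return FeatureMatrix(
        list(m.ids), list(m.columns), out,
        m.provenance + [{"op": "minmax_scale"}],
    )
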