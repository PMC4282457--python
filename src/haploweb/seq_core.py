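"""Sequence and alignment data model shared by all pipeline stages.

Provides the marker-sequence container, Kimura two-parameter (K2P)
distances with pairwise deletion, codon-position and consensus column
filters, and the marker-resolution check used to flag species pairs that a
slowly evolving marker cannot distinguish.

Column coordinates in every user-facing API are 1-based.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Marker",
    "Sequence",
    "Alignment",
    "K2PCounts",
    "DistanceMatrix",
    "SaturatedDistanceError",
    "IUPAC_TO_BASES",
    "BASES_TO_IUPAC",
    "k2p_counts",
    "k2p_from_counts",
    "k2p_distance",
    "distance_matrix",
    "filter_codon_positions",
    "consensus_filter",
    "assess_marker_resolution",
    "read_fasta",
    "write_fasta",
    "read_species_map",
    "write_species_map",
]


class Marker(str, Enum):
    """Molecular marker identity of a sequence."""

    ITS = "ITS"
    COI = "COI"
    RRNA_28S = "28S"
    RRNA_16S = "16S"


#: IUPAC two-fold ambiguity codes, used to collapse heterozygous diploid
#: positions into a single residue (and to expand them again).
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

_VALID_RESIDUES = frozenset("ACGT-N") | frozenset(IUPAC_TO_BASES)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

# numeric encoding for vectorised distance computation: A,G purines first
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}
_MISSING = 255


class SaturatedDistanceError(ValueError):
    """Raised when a K2P distance is undefined (log of a non-positive value)."""

    def __init__(self, pair: tuple[str, str] | None = None):
        self.pair = pair
        msg = "K2P distance saturated"
        if pair:
            msg += f" for pair {pair[0]!r}, {pair[1]!r}"
        super().__init__(msg)


@dataclass(frozen=True)
class Sequence:
    """One aligned marker sequence.

    Residues may contain gaps ('-'), missing data ('N') and the two-fold
    IUPAC ambiguity codes produced by direct sequencing of heterozygotes.
    """

    id: str
    residues: str
    marker: Marker = Marker.ITS

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """A list of equal-length sequences (columns are homologous sites)."""

    sequences: list[Sequence]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate sequence ids: {dup}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, seq_id: str) -> Sequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def column(self, pos: int) -> str:
        """Residues of 1-based column `pos`."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"column {pos} out of range 1..{self.length}")
        return "".join(s.residues[pos - 1] for s in self.sequences)

    def take_columns(self, positions: TypingSequence[int]) -> "Alignment":
        """Sub-alignment of the given 1-based columns, order preserved."""
        idx = [p - 1 for p in positions]
        return Alignment(
            [
                Sequence(s.id, "".join(s.residues[i] for i in idx), s.marker)
                for s in self.sequences
            ]
        )

    def encoded(self) -> np.ndarray:
        """(n_seq, n_col) uint8 matrix; ambiguity codes, gaps and N are missing.

        IUPAC heterozygote codes carry no single-haplotype state, so they are
        pairwise-deleted in distance computations, like gaps.
        """
        arr = np.full((len(self.sequences), self.length), _MISSING, dtype=np.uint8)
        for i, s in enumerate(self.sequences):
            for j, ch in enumerate(s.residues):
                arr[i, j] = _CODE.get(ch, _MISSING)
        return arr


@dataclass(frozen=True)
class K2PCounts:
    """Transition (P) and transversion (Q) proportions after pairwise deletion."""

    P: float
    Q: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError(f"invalid proportions P={self.P}, Q={self.Q}")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over sequence ids.

    Saturated (undefined) K2P distances are stored as +inf and flagged in
    ``saturated`` rather than raising, so callers can decide how to react.
    """

    ids: list[str]
    d: np.ndarray
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if self.saturated is None:
            self.saturated = ~np.isfinite(self.d)
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        mask = np.isfinite(self.d) & np.isfinite(self.d).T
        if not np.allclose(self.d[mask], self.d.T[mask], rtol=1e-9, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        self.d[mask] = (self.d[mask] + self.d.T[mask]) / 2.0

    @property
    def any_saturated(self) -> bool:
        return bool(self.saturated.any())

    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in zip(*np.nonzero(np.triu(self.saturated, 1))):
            out.append((self.ids[i], self.ids[j]))
        return out


# ---------------------------------------------------------------------------
# distances


def k2p_counts(a: Sequence, b: Sequence) -> K2PCounts:
    """Count transition/transversion proportions under pairwise deletion.

    Sites where either sequence has a gap, an N or an IUPAC ambiguity code
    are excluded from the comparison.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequences {a.id!r} ({len(a)}) and {b.id!r} ({len(b)}) differ in length"
        )
    ts = tv = n = 0
    for x, y in zip(a.residues, b.residues):
        if x not in _CODE or y not in _CODE:
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in _PURINES) == (y in _PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError(f"no comparable sites between {a.id!r} and {b.id!r}")
    return K2PCounts(P=ts / n, Q=tv / n, n_sites=n)


def k2p_from_counts(counts: K2PCounts) -> float:
    """K2P distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q); inf when saturated."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(a: Sequence, b: Sequence) -> float:
    """Pairwise-deletion K2P distance; +inf (flagged saturated) when undefined."""
    return k2p_from_counts(k2p_counts(a, b))


def _pq_matrices(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised P, Q proportions and comparable-site counts for all pairs."""
    valid = enc != _MISSING
    both = valid[:, None, :] & valid[None, :, :]
    n = both.sum(axis=2)
    a = enc[:, None, :]
    b = enc[None, :, :]
    diff = (a != b) & both
    # purines coded 0/1, pyrimidines 2/3: same class iff codes // 2 equal
    same_class = (a // 2) == (b // 2)
    ts = (diff & same_class).sum(axis=2)
    tv = (diff & ~same_class).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(n > 0, ts / np.maximum(n, 1), np.nan)
        Q = np.where(n > 0, tv / np.maximum(n, 1), np.nan)
    return P, Q, n


def distance_matrix(aln: Alignment, enc: np.ndarray | None = None) -> DistanceMatrix:
    """K2P distance matrix over an alignment (pairwise deletion, vectorised).

    Pairs with zero comparable sites raise; saturated pairs are flagged +inf.
    An optional pre-encoded matrix (``aln.encoded()`` with resampled columns)
    supports the bootstrap hot path.
    """
    if enc is None:
        enc = aln.encoded()
    P, Q, n = _pq_matrices(enc)
    if (n == 0).any() and len(aln) > 1:
        i, j = np.argwhere((n == 0) & ~np.eye(len(aln), dtype=bool))[0]
        raise ValueError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(
            (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
            - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
            np.inf,
        )
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(aln.ids), d=d)


# ---------------------------------------------------------------------------
# column filters


def filter_codon_positions(
    aln: Alignment, frame: int = 1, keep: Iterable[int] = (1, 2)
) -> Alignment:
    """Keep only columns at the given codon positions.

    `frame` is the 1-based column where the first full codon starts. Columns
    upstream of the frame start are assigned positions cyclically. The usual
    call drops 3rd positions of a protein-coding marker (keep={1, 2}).
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    if not keep <= {1, 2, 3}:
        raise ValueError(f"codon positions must be within {{1,2,3}}, got {sorted(keep)}")
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    if aln.length < frame:
        raise ValueError("alignment shorter than frame offset")
    cols = [c for c in range(1, aln.length + 1) if ((c - frame) % 3) + 1 in keep]
    return aln.take_columns(cols)


def consensus_filter(
    aln: Alignment, threshold: float = 50.0
) -> tuple[Alignment, int]:
    """Remove hypervariable columns, keeping those with a dominant character.

    A column is retained iff its modal character — gaps counted as
    characters — is carried by >= `threshold` percent of all sequences.
    Returns the filtered alignment and the retained-column count.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must lie in (0, 100]")
    n = len(aln)
    kept = []
    for c in range(1, aln.length + 1):
        counts = Counter(aln.column(c))
        modal = counts.most_common(1)[0][1]
        if 100.0 * modal / n >= threshold:
            kept.append(c)
    if not kept:
        raise ValueError("consensus filter removed every column")
    return aln.take_columns(kept), len(kept)


def assess_marker_resolution(
    aln: Alignment, species_map: Mapping[str, str]
) -> list[tuple[str, str]]:
    """Species pairs this marker cannot tell apart (identical residue strings).

    Returns sorted pairs (sp1, sp2), sp1 < sp2, for which at least one
    sequence string occurs in both species' sequence sets.
    """
    missing = [s.id for s in aln.sequences if s.id not in species_map]
    if missing:
        raise KeyError(f"ids absent from species map: {missing}")
    by_string: dict[str, set[str]] = {}
    for s in aln.sequences:
        by_string.setdefault(s.residues, set()).add(species_map[s.id])
    pairs: set[tuple[str, str]] = set()
    for species in by_string.values():
        for sp1 in species:
            for sp2 in species:
                if sp1 < sp2:
                    pairs.add((sp1, sp2))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, marker: Marker = Marker.ITS) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment(
        [Sequence(r.id, str(r.seq).upper(), marker) for r in records]
    )


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_species_map(path: str | Path) -> dict[str, str]:
    """TSV with columns individual_id, species (header optional)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "individual_id":
            continue
        if len(parts) < 2:
            raise ValueError(f"malformed species-map line: {line!r}")
        out[parts[0]] = parts[1]
    return out


def write_species_map(mapping: Mapping[str, str], path: str | Path) -> None:
    lines = ["individual_id\tspecies"]
    lines += [f"{k}\t{v}" for k, v in sorted(mapping.items())]
    Path(path).write_text("\n".join(lines) + "\n")
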