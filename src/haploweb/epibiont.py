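"""In-silico screening of 16S rRNA sequences for Thiothrix epibionts.

Covers the molecular side of epibiont detection: matching the
Thiothrix-specific primers and probes against templates, predicting the
amplicon a primer pair would produce, assigning query sequences to
epibiont clades (T1–T4, mat) by percent identity against a labelled
reference set, resolving two-sequence mixtures by comparison with
reference sequences, and the rarefaction curve used to judge clone-library
sampling depth.

Clade assignment replaces a database BLAST with identity against a
user-extensible labelled reference FASTA, preserving the top-hit decision
rule while keeping the pipeline self-contained.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import yaml
from Bio import Align
from scipy.special import gammaln

from .deconvolution import MixedTrace
from .seq_core import Marker, Sequence

__all__ = [
    "OligoRole",
    "Oligo",
    "ReferenceSet",
    "CladeAssignment",
    "Amplicon",
    "RarefactionPoint",
    "packaged_oligos",
    "match_oligo",
    "predict_amplicon",
    "pairwise_identity",
    "assign_clade",
    "resolve_mixture_by_reference",
    "rarefaction_curve",
    "expected_richness",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class OligoRole(str, Enum):
    FORWARD_PRIMER = "forward_primer"
    REVERSE_PRIMER = "reverse_primer"
    PROBE = "probe"
    COMPETITOR = "competitor"


@dataclass(frozen=True)
class Oligo:
    """A PCR primer or hybridization probe, written 5'->3'."""

    name: str
    bases: str
    role: OligoRole

    def __post_init__(self) -> None:
        if set(self.bases) - set("ACGT"):
            raise ValueError(f"{self.name}: oligo bases must be plain ACGT")
        if len(self.bases) < 10:
            raise ValueError(f"{self.name}: oligo shorter than 10 nt")

    def __len__(self) -> int:
        return len(self.bases)


def packaged_oligos() -> dict[str, Oligo]:
    """The Thiothrix-specific primers and probes shipped with the package."""
    text = (
        importlib.resources.files("haploweb.data") / "oligos.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {
        name: Oligo(
            name=name,
            bases=entry["bases"].replace(" ", "").upper(),
            role=OligoRole(entry["role"]),
        )
        for name, entry in raw.items()
    }


@dataclass
class ReferenceSet:
    """Labelled 16S reference sequences for clade assignment.

    Clade labels follow the epibiont lineages (T1–T4), free-living mat
    sequences ('mat') and 'other'. Sequences may be pre-aligned (equal
    length, possibly gapped) or unaligned; identity computation adapts.
    """

    sequences: list[Sequence]
    clades: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s.id for s in self.sequences if s.id not in self.clades]
        if missing:
            raise ValueError(f"references without clade label: {missing}")
        if not self.sequences:
            raise ValueError("reference set must be non-empty")

    @property
    def clade_labels(self) -> set[str]:
        return set(self.clades.values())

    def of_clade(self, clade: str) -> list[Sequence]:
        return [s for s in self.sequences if self.clades[s.id] == clade]


class AssignmentStatus(str, Enum):
    ASSIGNED = "assigned"
    AMBIGUOUS = "ambiguous"
    NON_THIOTHRIX = "non_thiothrix"


@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    best_clade: str
    identity: float
    margin: float
    status: AssignmentStatus

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must lie in [0, 100]")
        if self.margin < 0.0:
            raise ValueError("margin must be >= 0")


@dataclass(frozen=True)
class Amplicon:
    length: int
    start: int  # 1-based, 5' end of the forward primer site
    end: int    # 1-based, 5' end of the reverse primer site on the template
    fwd_mismatches: int
    rev_mismatches: int


@dataclass(frozen=True)
class RarefactionPoint:
    n: int
    expected_otus: float


# ---------------------------------------------------------------------------
# oligo matching and amplicon prediction


def match_oligo(
    oligo: Oligo, template: Sequence, max_mismatch: int = 0
) -> list[tuple[int, str, int]]:
    """Ungapped matches of an oligo against a gap-free template.

    Forward primers and probes scan the given (plus) strand; reverse
    primers scan for the reverse complement of the oligo on the plus
    strand, i.e. their binding site on the opposite strand. Returns
    (position 1-based on the template, strand, mismatches), 0-mismatch
    hits first, then by position.
    """
    tpl = template.residues
    if "-" in tpl:
        raise ValueError(f"template {template.id!r} must be gap-free")
    probe = (
        _revcomp(oligo.bases)
        if oligo.role is OligoRole.REVERSE_PRIMER
        else oligo.bases
    )
    strand = "-" if oligo.role is OligoRole.REVERSE_PRIMER else "+"
    k = len(probe)
    if k > len(tpl):
        return []
    tarr = np.frombuffer(tpl.encode(), dtype=np.uint8)
    parr = np.frombuffer(probe.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(tarr, k)
    mismatches = (windows != parr).sum(axis=1)
    hits = [
        (int(pos) + 1, strand, int(mm))
        for pos, mm in enumerate(mismatches)
        if mm <= max_mismatch
    ]
    hits.sort(key=lambda h: (h[2] > 0, h[0]))
    return hits


def predict_amplicon(
    fwd: Oligo,
    rev: Oligo,
    template: Sequence,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Amplicons the primer pair would produce from a template.

    An amplicon spans from the 5' end of the forward-primer site to the
    5' end of the reverse primer's binding site on the opposite strand
    (the most 3' base of its site on the template), inclusive. Only
    orientation-consistent pairs (reverse site downstream of the forward
    site) qualify; the list is sorted by length, shortest (nearest valid
    pair) first. Empty list when no pair exists.
    """
    if fwd.role is not OligoRole.FORWARD_PRIMER:
        raise ValueError(f"{fwd.name} is not a forward primer")
    if rev.role is not OligoRole.REVERSE_PRIMER:
        raise ValueError(f"{rev.name} is not a reverse primer")
    fhits = match_oligo(fwd, template, max_mismatch)
    rhits = match_oligo(rev, template, max_mismatch)
    out = []
    for fpos, _, fmm in fhits:
        for rpos, _, rmm in rhits:
            rend = rpos + len(rev) - 1  # 5' end of the reverse primer itself
            if rpos >= fpos and rend > fpos:
                out.append(
                    Amplicon(
                        length=rend - fpos + 1,
                        start=fpos,
                        end=rend,
                        fwd_mismatches=fmm,
                        rev_mismatches=rmm,
                    )
                )
    out.sort(key=lambda a: (a.length, a.start))
    return out


# ---------------------------------------------------------------------------
# identity and clade assignment

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -0.5
# end-gap-free: unsequenced ends should not count against identity
_aligner.end_insertion_score = 0.0
_aligner.end_deletion_score = 0.0


def pairwise_identity(a: Sequence, b: Sequence) -> float:
    """Percent identity between two sequences.

    Pre-aligned inputs (equal length, at least one gap or by equal-length
    convention) are compared column-wise over columns where both are
    non-gap. Unaligned inputs are globally aligned with end-gap-free
    scoring (match=1, mismatch=0) and identity taken over the ungapped
    aligned columns.
    """
    if len(a) == len(b):
        same = total = 0
        for x, y in zip(a.residues, b.residues):
            if x == "-" or y == "-":
                continue
            total += 1
            if x == y:
                same += 1
        if total == 0:
            return 0.0
        return 100.0 * same / total
    s1, s2 = a.degapped(), b.degapped()
    aln = _aligner.align(s1, s2)[0]
    t, q = str(aln[0]), str(aln[1])
    same = total = 0
    for x, y in zip(t, q):
        if x == "-" or y == "-":
            continue
        total += 1
        if x == y:
            same += 1
    return 100.0 * same / total if total else 0.0


def assign_clade(
    query: Sequence,
    refs: ReferenceSet,
    assign_threshold: float = 90.0,
    margin_threshold: float = 1.0,
) -> CladeAssignment:
    """Assign a query to the clade of its top-identity reference.

    status is ``non_thiothrix`` when the best identity falls below
    `assign_threshold` percent, ``ambiguous`` when the margin over the
    best other clade falls below `margin_threshold` percentage points.
    """
    best_by_clade: dict[str, float] = {}
    for ref in refs.sequences:
        ident = pairwise_identity(query, ref)
        clade = refs.clades[ref.id]
        if ident > best_by_clade.get(clade, -1.0):
            best_by_clade[clade] = ident
    ranked = sorted(best_by_clade.items(), key=lambda kv: (-kv[1], kv[0]))
    best_clade, best_ident = ranked[0]
    margin = best_ident - ranked[1][1] if len(ranked) > 1 else best_ident
    if best_ident < assign_threshold:
        status = AssignmentStatus.NON_THIOTHRIX
    elif margin < margin_threshold:
        status = AssignmentStatus.AMBIGUOUS
    else:
        status = AssignmentStatus.ASSIGNED
    return CladeAssignment(
        query_id=query.id,
        best_clade=best_clade,
        identity=best_ident,
        margin=max(margin, 0.0),
        status=status,
    )


# ---------------------------------------------------------------------------
# mixture resolution


def _superpose(a: str, b: str) -> list[frozenset[str]]:
    L = max(len(a), len(b))
    out = []
    for i in range(L):
        s = set()
        if i < len(a):
            s.add(a[i])
        if i < len(b):
            s.add(b[i])
        out.append(frozenset(s))
    return out


def resolve_mixture_by_reference(
    fwd: MixedTrace, refs: ReferenceSet
) -> tuple[Sequence, Sequence] | None:
    """Resolve a two-sequence mixture by comparison with reference sequences.

    Searches all pairs of (degapped) reference sequences whose 5'-aligned
    superposition reproduces every base-set of the trace. With no double
    peak, the trace is a single sequence and the matching reference (or the
    read itself) is returned twice. Returns None on failure; the caller can
    consult ``resolve_mixture_by_reference.last_near_miss`` for the
    smallest violation count seen.
    """
    seqs = [(r.id, r.degapped()) for r in refs.sequences]
    tr = fwd.positions
    if fwd.n_double_peaks == 0:
        read = "".join(next(iter(s)) for s in tr)
        for rid, s in seqs:
            if s == read:
                hit = Sequence(rid, s, Marker.RRNA_16S)
                resolve_mixture_by_reference.last_near_miss = 0  # type: ignore[attr-defined]
                return hit, hit
        hit = Sequence(fwd.id, read, Marker.RRNA_16S)
        resolve_mixture_by_reference.last_near_miss = 0  # type: ignore[attr-defined]
        return hit, hit
    best: tuple[int, tuple[str, str]] | None = None
    for i, (id1, s1) in enumerate(seqs):
        for id2, s2 in seqs[i:]:
            if max(len(s1), len(s2)) != len(tr):
                continue
            sup = _superpose(s1, s2)
            viol = sum(1 for x, y in zip(sup, tr) if x != y)
            if best is None or viol < best[0]:
                best = (viol, (id1, id2))
    if best is None or best[0] > 0:
        resolve_mixture_by_reference.last_near_miss = (  # type: ignore[attr-defined]
            best[0] if best else None
        )
        return None
    id1, id2 = best[1]
    r1 = next(r for r in refs.sequences if r.id == id1)
    r2 = next(r for r in refs.sequences if r.id == id2)
    resolve_mixture_by_reference.last_near_miss = 0  # type: ignore[attr-defined]
    return (
        Sequence(r1.id, r1.degapped(), Marker.RRNA_16S),
        Sequence(r2.id, r2.degapped(), Marker.RRNA_16S),
    )


# ---------------------------------------------------------------------------
# rarefaction


def rarefaction_curve(
    counts: TypingSequence[int], step: int = 1
) -> list[RarefactionPoint]:
    """Expected OTU richness in random subsamples of a clone library.

    For per-OTU abundances N_i summing to N, the expected number of OTUs
    in a random subsample of n clones is the hypergeometric expectation

        E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n)),

    computed stably in log space. Points are reported at n = step,
    2*step, ..., N (N always included).
    """
    counts = list(counts)
    if not counts or any(c <= 0 or int(c) != c for c in counts):
        raise ValueError("counts must be positive integers")
    if step < 1:
        raise ValueError("step must be >= 1")
    N = int(sum(counts))
    ns = list(range(step, N + 1, step))
    if not ns or ns[-1] != N:
        ns.append(N)
    return [RarefactionPoint(n=n, expected_otus=_expected_otus(counts, n, N)) for n in ns]


def expected_richness(counts: TypingSequence[int], n: int) -> float:
    """E[S_n]: expected OTU count in a random subsample of n clones."""
    counts = list(counts)
    if not counts or any(c <= 0 or int(c) != c for c in counts):
        raise ValueError("counts must be positive integers")
    return _expected_otus(counts, n, int(sum(counts)))


def _expected_otus(counts: TypingSequence[int], n: int, N: int) -> float:
    if n > N:
        raise ValueError(f"subsample size {n} exceeds total {N}")
    total = 0.0
    for Ni in counts:
        if N - Ni < n:
            total += 1.0  # the OTU cannot be missed
            continue
        log_absent = (
            gammaln(N - Ni + 1)
            - gammaln(n + 1)
            - gammaln(N - Ni - n + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )
        total += 1.0 - float(np.exp(log_absent))
    return total


def write_rarefaction_table(
    points: Iterable[RarefactionPoint], path: str | Path
) -> None:
    lines = ["n\texpected_otus"]
    lines += [f"{p.n}\t{p.expected_otus:.4f}" for p in points]
    Path(path).write_text("\n".join(lines) + "\n")


def write_clade_report(
    assignments: Iterable[CladeAssignment], path: str | Path
) -> None:
    lines = ["query_id\tbest_clade\tidentity\tmargin\tstatus"]
    for a in assignments:
        lines.append(
            f"{a.query_id}\t{a.best_clade}\t{a.identity:.2f}\t{a.margin:.2f}\t{a.status.value}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
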