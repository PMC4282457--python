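"""Resolve length-variant heterozygotes from superposed Sanger traces.

A diploid individual whose two alleles differ by an indel produces, when
sequenced directly, a readable prefix followed by frame-shifted double
peaks. Sequencing the same product from both ends gives two superpositions
of the same two haplotypes: the forward read is 5'-aligned (the shifted
tail is at the 3' end) and the reverse read, once re-complemented into
forward coordinates, is 3'-aligned. Knowing the length difference Δ, the
two reads form a system of pairwise constraints that usually pins down both
haplotypes exactly.

The input is not a raw chromatogram but a per-position base-set call: at
each position the set of one or two bases observed as peaks.

Candidate Δ values are ranked by a compatibility score (the number of
positions at which the 5'- and 3'-aligned constraint systems are mutually
satisfiable); haplotypes are then recovered by constraint propagation from
singleton anchors, with a deterministic tie-break and an explicit
uniqueness flag when the system is underdetermined.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from .seq_core import Marker, Sequence

__all__ = [
    "Orientation",
    "MixedTrace",
    "ShiftScore",
    "DeconvolutionResult",
    "NoLengthVariance",
    "DeconvolutionError",
    "score_shifts",
    "deconvolve",
    "simulate_superposition",
    "read_trace",
    "write_trace",
]

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


class NoLengthVariance(ValueError):
    """Both traces are all-singleton and equal length: nothing to unravel."""


class DeconvolutionError(ValueError):
    """No haplotype pair satisfies the constraint system."""

    def __init__(self, position: int, msg: str = ""):
        #: first contradictory position (1-based)
        self.position = position
        super().__init__(
            msg or f"contradiction at position {position}: no consistent haplotype pair"
        )


@dataclass(frozen=True)
class MixedTrace:
    """Per-position candidate base-sets from a superposed chromatogram.

    Reverse-orientation traces are stored already re-complemented into
    forward coordinates of the 3'-aligned superposition, so the solver works
    in a single coordinate system; strand handling lives in I/O.
    """

    id: str
    positions: tuple[frozenset[str], ...]
    orientation: Orientation

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"trace {self.id!r}: empty")
        for i, s in enumerate(self.positions):
            if not s or not s <= _BASES or len(s) > 2:
                raise ValueError(
                    f"trace {self.id!r} position {i + 1}: invalid base-set {sorted(s)}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_double_peaks(self) -> int:
        return sum(1 for s in self.positions if len(s) == 2)


@dataclass(frozen=True)
class ShiftScore:
    """Compatibility score of one candidate length difference Δ."""

    delta: int
    score: int


@dataclass(frozen=True)
class DeconvolutionResult:
    haplotype_long: Sequence
    haplotype_short: Sequence
    delta: int
    unique: bool

    def __post_init__(self) -> None:
        if len(self.haplotype_long) - len(self.haplotype_short) != self.delta:
            raise ValueError("length difference does not equal delta")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset(
            {self.haplotype_long.residues, self.haplotype_short.residues}
        )


def _check_traces(fwd: MixedTrace, rev: MixedTrace) -> None:
    if fwd.orientation is not Orientation.FORWARD:
        raise ValueError("first trace must be forward-orientation")
    if rev.orientation is not Orientation.REVERSE:
        raise ValueError("second trace must be reverse-orientation")


def score_shifts(
    fwd: MixedTrace, rev: MixedTrace, max_delta: int = 3
) -> list[ShiftScore]:
    """Rank candidate length differences Δ = 1..max_delta by compatibility.

    Both superpositions contain the long haplotype X at every position, so
    comparing same-position base-sets cannot discriminate. What does is
    the short haplotype Y, which appears at forward position i and reverse
    position i+Δ: for each candidate Δ the score counts the positions at
    which the constraints are mutually satisfiable, i.e.
    F[i] ∩ R[i+Δ] ≠ ∅ for i < L−Δ (a value for Y[i] exists) and |F[i]| = 1
    for the forward tail i ≥ L−Δ (only X extends there). The true Δ of a
    clean two-haplotype superposition scores the full trace length, wrong
    shifts generically less. Returned sorted by decreasing score, ties by
    ascending Δ.
    """
    _check_traces(fwd, rev)
    if max_delta < 1:
        raise ValueError("max_delta must be >= 1")
    if abs(len(fwd) - len(rev)) > max_delta:
        raise ValueError(
            f"trace lengths {len(fwd)} vs {len(rev)} differ by more than max_delta"
        )
    if (
        len(fwd) == len(rev)
        and fwd.n_double_peaks == 0
        and rev.n_double_peaks == 0
    ):
        raise NoLengthVariance(
            f"trace {fwd.id!r}: all-singleton equal-length reads show no length variance"
        )
    L = min(len(fwd), len(rev))
    scores = []
    for delta in range(1, max_delta + 1):
        s = 0
        for i in range(L):
            if i < L - delta:
                if fwd.positions[i] & rev.positions[i + delta]:
                    s += 1
            else:
                if len(fwd.positions[i]) == 1:
                    s += 1
        scores.append(ShiftScore(delta=delta, score=s))
    scores.sort(key=lambda x: (-x.score, x.delta))
    return scores


def deconvolve(fwd: MixedTrace, rev: MixedTrace, delta: int) -> DeconvolutionResult:
    """Recover the two haplotypes given the length difference Δ.

    With X the long haplotype (length L) and Y the short one (length L−Δ),
    the forward trace imposes {X[i], Y[i]} = F[i] (tail: {X[i]} = F[i]) and
    the reverse trace {X[i], Y[i−Δ]} = R[i] (head: {X[i]} = R[i]). Each
    doubleton constraint determines one member given the other, so values
    propagate along chains seeded at singleton positions. Chains never
    reached by an anchor are symmetric; a deterministic choice (smallest
    base at the leftmost free position) is then made and the result flagged
    ``unique=False``.

    The Δ=0 path handles fully homozygous traces: both haplotypes equal the
    singleton read.
    """
    _check_traces(fwd, rev)
    F, R = fwd.positions, rev.positions
    if delta == 0:
        # equal-length pair: both reads superpose the same two haplotypes
        # in the same frame. Singleton positions are shared; at double
        # peaks the assignment is symmetric (no anchor can break the tie),
        # so a deterministic representative is returned, flagged non-unique.
        # Genuine phase resolution of such mixtures is the phasing module's
        # job.
        if len(F) != len(R):
            raise ValueError("delta=0 requires equal-length traces")
        xs, ys = [], []
        symmetric = False
        for i, (f, r) in enumerate(zip(F, R)):
            if f != r:
                raise DeconvolutionError(i + 1, f"position {i + 1}: forward and "
                                         "reverse base-sets disagree at delta=0")
            if len(f) == 1:
                xs.append(next(iter(f)))
                ys.append(next(iter(f)))
            else:
                lo, hi = sorted(f)
                xs.append(lo)
                ys.append(hi)
                symmetric = True
        return DeconvolutionResult(
            haplotype_long=Sequence(fwd.id + "_a", "".join(xs), Marker.ITS),
            haplotype_short=Sequence(fwd.id + "_b", "".join(ys), Marker.ITS),
            delta=0,
            unique=not symmetric,
        )
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if len(F) != len(R):
        raise ValueError(
            "forward and reverse superpositions of one PCR product must have "
            f"equal lengths, got {len(F)} vs {len(R)}"
        )
    L = len(F)
    if delta >= L:
        raise ValueError(f"delta {delta} not smaller than trace length {L}")
    LY = L - delta

    X: list[str | None] = [None] * L
    Y: list[str | None] = [None] * LY
    made_choice = False

    def assign(vec, idx, base, pos):
        if vec[idx] is None:
            vec[idx] = base
            return True
        if vec[idx] != base:
            raise DeconvolutionError(pos + 1)
        return False

    def propagate_from(queue: list[tuple[str, int]]) -> None:
        # worklist of newly assigned variables; each doubleton constraint
        # determines the partner, singletons are checked for membership
        while queue:
            var, idx = queue.pop()
            if var == "X":
                i = idx
                f = F[i] if i < L else None
                if f is not None:
                    if X[i] not in f:
                        raise DeconvolutionError(i + 1)
                    if i < LY:
                        other = f - {X[i]} if len(f) == 2 else f
                        if assign(Y, i, next(iter(other)), i):
                            queue.append(("Y", i))
                r = R[i]
                if X[i] not in r:
                    raise DeconvolutionError(i + 1)
                if i >= delta:
                    other = r - {X[i]} if len(r) == 2 else r
                    if assign(Y, i - delta, next(iter(other)), i):
                        queue.append(("Y", i - delta))
            else:
                j = idx
                f = F[j]
                if Y[j] not in f:
                    raise DeconvolutionError(j + 1)
                other = f - {Y[j]} if len(f) == 2 else f
                if assign(X, j, next(iter(other)), j):
                    queue.append(("X", j))
                r = R[j + delta]
                if Y[j] not in r:
                    raise DeconvolutionError(j + delta + 1)
                other = r - {Y[j]} if len(r) == 2 else r
                if assign(X, j + delta, next(iter(other)), j + delta):
                    queue.append(("X", j + delta))

    # seed from singleton anchors, deterministic left-to-right order
    queue: list[tuple[str, int]] = []
    for i in range(L):
        if len(F[i]) == 1:
            base = next(iter(F[i]))
            if i >= LY:  # forward tail: X only
                if assign(X, i, base, i):
                    queue.append(("X", i))
            else:  # singleton means X[i] == Y[i] == base
                if assign(X, i, base, i):
                    queue.append(("X", i))
                if assign(Y, i, base, i):
                    queue.append(("Y", i))
        if len(R[i]) == 1:
            base = next(iter(R[i]))
            if i < delta:
                if assign(X, i, base, i):
                    queue.append(("X", i))
            else:
                if assign(X, i, base, i):
                    queue.append(("X", i))
                if assign(Y, i - delta, base, i):
                    queue.append(("Y", i - delta))
    propagate_from(queue)

    # resolve symmetric (never-anchored) chains deterministically
    for i in range(L):
        if X[i] is None:
            made_choice = True
            choice = min(F[i] if i < L else R[i])
            assign(X, i, choice, i)
            propagate_from([("X", i)])
    for j in range(LY):
        if Y[j] is None:  # pragma: no cover - chains touch X, handled above
            made_choice = True
            assign(Y, j, min(F[j]), j)
            propagate_from([("Y", j)])

    x = "".join(X)  # type: ignore[arg-type]
    y = "".join(Y)  # type: ignore[arg-type]
    # full verification against every base-set of both traces
    for i in range(L):
        fset = {x[i]} | ({y[i]} if i < LY else set())
        if fset != set(F[i]):
            raise DeconvolutionError(i + 1)
        rset = {x[i]} | ({y[i - delta]} if i >= delta else set())
        if rset != set(R[i]):
            raise DeconvolutionError(i + 1)
    return DeconvolutionResult(
        haplotype_long=Sequence(fwd.id + "_a", x, Marker.ITS),
        haplotype_short=Sequence(fwd.id + "_b", y, Marker.ITS),
        delta=delta,
        unique=not made_choice,
    )


def simulate_superposition(x: Sequence, y: Sequence) -> tuple[MixedTrace, MixedTrace]:
    """Forward and reverse superposed traces of two gap-free haplotypes.

    The longer haplotype anchors both coordinate systems; the forward trace
    is the 5'-aligned union of the two reads, the reverse trace the
    3'-aligned union (already expressed in forward coordinates).
    """
    for s in (x, y):
        if "-" in s.residues or set(s.residues) - _BASES:
            raise ValueError(f"haplotype {s.id!r} must be gap-free ACGT")
    if len(x) == len(y):
        raise ValueError(
            "equal-length haplotypes produce no frame shift; use the phasing module"
        )
    if len(x) < len(y):
        x, y = y, x
    L, LY = len(x), len(y)
    delta = L - LY
    fwd = tuple(
        frozenset({x.residues[i]} | ({y.residues[i]} if i < LY else set()))
        for i in range(L)
    )
    rev = tuple(
        frozenset({x.residues[i]} | ({y.residues[i - delta]} if i >= delta else set()))
        for i in range(L)
    )
    return (
        MixedTrace(id=x.id, positions=fwd, orientation=Orientation.FORWARD),
        MixedTrace(id=x.id, positions=rev, orientation=Orientation.REVERSE),
    )


# ---------------------------------------------------------------------------
# trace file I/O
#
# Format: a header line `#id=<id> orientation=<forward|reverse>` followed by
# one position per line, bases comma-separated (e.g. `A` or `A,G`). Reverse
# traces on disk are written 5'->3' as read off the reverse chromatogram and
# re-complemented into forward coordinates at parse time.


def read_trace(path: str | Path) -> MixedTrace:
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing trace header")
    header = dict(
        tok.split("=", 1) for tok in lines[0].lstrip("#").split() if "=" in tok
    )
    trace_id = header.get("id")
    orient = header.get("orientation")
    if not trace_id or orient not in ("forward", "reverse"):
        raise ValueError(f"{path}: malformed header {lines[0]!r}")
    sets = [
        frozenset(b.strip().upper() for b in ln.split(","))
        for ln in lines[1:]
    ]
    if orient == "reverse":
        # reverse-complement into forward coordinates of the superposition
        sets = [frozenset(b.translate(_COMPLEMENT) for b in s) for s in reversed(sets)]
    return MixedTrace(
        id=trace_id,
        positions=tuple(sets),
        orientation=Orientation(orient),
    )


def write_trace(trace: MixedTrace, path: str | Path) -> None:
    sets: Iterable[frozenset[str]] = trace.positions
    if trace.orientation is Orientation.REVERSE:
        sets = [
            frozenset(b.translate(_COMPLEMENT) for b in s)
            for s in reversed(list(sets))
        ]
    lines = [f"#id={trace.id} orientation={trace.orientation.value}"]
    lines += [",".join(sorted(s)) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")
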