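"""Haplotype phasing of equal-length heterozygotes by Clark's parsimony method.

Diploid individuals directly sequenced for a nuclear marker yield, at
heterozygous positions, IUPAC two-base ambiguity codes. Clark's method
seeds a pool of known haplotypes from unambiguous individuals (full
homozygotes, and single-site heterozygotes whose phase is free) and then
repeatedly resolves any remaining genotype that is compatible with a known
haplotype, adding the complementary haplotype to the pool, until a
fixpoint.

The method is order-dependent; this implementation fixes the order to
(ascending heterozygosity count, then lexicographic individual id).
Among multiple compatible known haplotypes it prefers, by parsimony, a
resolution whose complementary haplotype is itself already known (no new
haplotype introduced), then the known haplotype with the highest current
usage count, ties broken lexicographically. Individuals resolvable in
more than one way are resolved but flagged ambiguous; individuals never
resolved are reported as unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .seq_core import (
    BASES_TO_IUPAC,
    IUPAC_TO_BASES,
    Alignment,
    Marker,
    Sequence,
)

__all__ = [
    "Genotype",
    "HaplotypeSet",
    "PhaseResult",
    "genotypes_from_iupac",
    "collapse_to_iupac",
    "seed_unambiguous",
    "clark_phase",
    "phased_sequences",
    "write_phase_report",
]


@dataclass
class Genotype:
    """A diploid individual's marker genotype as per-site allele pairs.

    ``sites[i]`` is a frozenset of one (homozygous) or two (heterozygous)
    alleles at the i-th alignment column. All individuals of a cohort share
    the same ordered site list.
    """

    individual_id: str
    sites: tuple[frozenset[str], ...]
    resolved: tuple[str, str] | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        for i, s in enumerate(self.sites):
            if not 1 <= len(s) <= 2:
                raise ValueError(
                    f"{self.individual_id}: site {i + 1} has {len(s)} alleles"
                )

    @property
    def n_het(self) -> int:
        return sum(1 for s in self.sites if len(s) == 2)

    def consistent_with(self, pair: tuple[str, str]) -> bool:
        """Site-wise multiset equality of a haplotype pair with this genotype."""
        a, b = pair
        if len(a) != len(self.sites) or len(b) != len(self.sites):
            return False
        return all(
            frozenset({a[i], b[i]}) == s for i, s in enumerate(self.sites)
        )

    def complement_of(self, hap: str) -> str | None:
        """The haplotype that pairs with `hap` to give this genotype, if any."""
        if len(hap) != len(self.sites):
            return None
        out = []
        for i, s in enumerate(self.sites):
            if hap[i] not in s:
                return None
            if len(s) == 2:
                out.append(next(iter(s - {hap[i]})))
            else:
                out.append(hap[i])
        return "".join(out)


@dataclass
class HaplotypeSet:
    """Known haplotypes with provenance: homozygote, single_het or inferred."""

    known: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)
    usage: dict[str, int] = field(default_factory=dict)

    def add(self, hap: str, how: str) -> None:
        if hap not in self.known:
            self.known.add(hap)
            self.provenance[hap] = how
            self.usage.setdefault(hap, 0)

    def use(self, hap: str) -> None:
        self.usage[hap] = self.usage.get(hap, 0) + 1

    @property
    def empty(self) -> bool:
        return not self.known


@dataclass
class PhaseResult:
    genotypes: list[Genotype]
    haplotypes: HaplotypeSet
    unresolved_ids: list[str]

    @property
    def resolved_pairs(self) -> dict[str, tuple[str, str]]:
        return {
            g.individual_id: g.resolved
            for g in self.genotypes
            if g.resolved is not None
        }


def genotypes_from_iupac(aln: Alignment) -> list[Genotype]:
    """Genotypes from an aligned FASTA with IUPAC-collapsed heterozygotes."""
    out = []
    for s in aln.sequences:
        sites = []
        for ch in s.residues:
            if ch == "-":
                sites.append(frozenset("-"))
            elif ch in IUPAC_TO_BASES:
                sites.append(IUPAC_TO_BASES[ch])
            else:
                raise ValueError(
                    f"{s.id}: residue {ch!r} is not phaseable (N unsupported)"
                )
        out.append(Genotype(individual_id=s.id, sites=tuple(sites)))
    return out


def collapse_to_iupac(a: str, b: str) -> str:
    """Collapse two equal-length allele strings into one IUPAC sequence."""
    if len(a) != len(b):
        raise ValueError("alleles must be equal length (length variants go "
                         "through trace deconvolution)")
    out = []
    for x, y in zip(a, b):
        if x == y:
            out.append(x)
        else:
            code = BASES_TO_IUPAC.get(frozenset({x, y}))
            if code is None:
                raise ValueError(f"cannot collapse pair {x}/{y}")
            out.append(code)
    return "".join(out)


def seed_unambiguous(genotypes: Iterable[Genotype]) -> HaplotypeSet:
    """Clark step 1: haplotypes of homozygotes and single-site heterozygotes."""
    hs = HaplotypeSet()
    for g in genotypes:
        if g.n_het == 0:
            hap = "".join(next(iter(s)) for s in g.sites)
            hs.add(hap, "homozygote")
            g.resolved = (hap, hap)
        elif g.n_het == 1:
            het_i = next(i for i, s in enumerate(g.sites) if len(s) == 2)
            a1, a2 = sorted(g.sites[het_i])
            base = [next(iter(s)) if len(s) == 1 else "" for s in g.sites]
            h1 = "".join(base[:het_i]) + a1 + "".join(base[het_i + 1:])
            h2 = "".join(base[:het_i]) + a2 + "".join(base[het_i + 1:])
            hs.add(h1, "single_het")
            hs.add(h2, "single_het")
            g.resolved = tuple(sorted((h1, h2)))  # type: ignore[assignment]
    return hs


def clark_phase(
    genotypes: list[Genotype], seed: HaplotypeSet | None = None
) -> PhaseResult:
    """Iteratively resolve genotypes against the growing known-haplotype pool.

    Passes run to a fixpoint; within a pass, unresolved genotypes are
    visited in (n_het, individual_id) order. A genotype compatible with
    more than one known haplotype (yielding different pairs) is resolved
    with the preferred one and flagged ambiguous.
    """
    if seed is None:
        seed = seed_unambiguous(genotypes)
    hs = seed
    for g in genotypes:
        if g.resolved is not None:
            for h in set(g.resolved):
                hs.use(h)

    changed = True
    while changed:
        changed = False
        pending = sorted(
            (g for g in genotypes if g.resolved is None),
            key=lambda g: (g.n_het, g.individual_id),
        )
        for g in pending:
            candidates = []
            for h in hs.known:
                comp = g.complement_of(h)
                if comp is not None:
                    candidates.append((h, comp))
            if not candidates:
                continue
            # parsimony: prefer resolutions introducing no new haplotype,
            # then the most-used known haplotype, then lexicographic
            candidates.sort(
                key=lambda hc: (
                    hc[1] not in hs.known,
                    -hs.usage.get(hc[0], 0),
                    hc[0],
                )
            )
            h, comp = candidates[0]
            distinct_pairs = {frozenset(hc) for hc in candidates}
            g.resolved = tuple(sorted((h, comp)))  # type: ignore[assignment]
            g.ambiguous = len(distinct_pairs) > 1
            hs.add(comp, "inferred")
            hs.use(h)
            hs.use(comp)
            changed = True

    unresolved = sorted(
        g.individual_id for g in genotypes if g.resolved is None
    )
    return PhaseResult(genotypes=genotypes, haplotypes=hs, unresolved_ids=unresolved)


def phased_sequences(
    result: PhaseResult, marker: Marker = Marker.ITS
) -> list[Sequence]:
    """Phased haplotypes as sequences with "_a"/"_b" suffixed ids.

    Unresolved individuals are omitted; they enter the haploweb separately
    as their ambiguity-collapsed sequence, flagged.
    """
    out = []
    for g in result.genotypes:
        if g.resolved is None:
            continue
        a, b = g.resolved
        out.append(Sequence(g.individual_id + "_a", a, marker))
        out.append(Sequence(g.individual_id + "_b", b, marker))
    return out


def write_phase_report(result: PhaseResult, path: str | Path) -> None:
    lines = ["individual_id\tn_het\tstatus\thaplotype_a\thaplotype_b"]
    for g in sorted(result.genotypes, key=lambda g: g.individual_id):
        if g.resolved is None:
            lines.append(f"{g.individual_id}\t{g.n_het}\tunresolved\t.\t.")
        else:
            status = "ambiguous" if g.ambiguous else "resolved"
            lines.append(
                f"{g.individual_id}\t{g.n_het}\t{status}\t{g.resolved[0]}\t{g.resolved[1]}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
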