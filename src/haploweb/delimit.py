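"""Haplowebs and fields for recombination (FFR) species delimitation.

A haploweb is a haplotype network or tree augmented with connections
between haplotypes found co-occurring within heterozygous individuals.
Because co-occurrence within a diploid individual demonstrates that two
haplotypes meet in the same gene pool, the connected components of the
co-occurrence graph — the fields for recombination — are species
hypotheses. Haplotypes are compared as exact strings after gap
normalization (gap characters stripped); the delimitation is
co-occurrence-based, not distance-based, so no similarity threshold is
involved.

Congruence with an independent marker (e.g. a mitochondrial haplotree) is
reported via the adjusted Rand index over shared individuals and a
per-FFR monophyly check in the supplied tree; conflicting partitions are
reported, never auto-merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
from sklearn.metrics import adjusted_rand_score

from .njtree import Tree

__all__ = [
    "HaplowebGraph",
    "SpeciesPartition",
    "build_haploweb",
    "delimit_ffrs",
    "partition_congruence",
    "plot_haploweb",
    "write_edge_list",
    "write_species_table",
]


@dataclass
class HaplowebGraph:
    """Haplotype co-occurrence graph.

    Nodes are distinct (gap-normalized) haplotype strings with
    multiplicity; an edge joins the two haplotypes of every heterozygous
    individual and is labelled with the supporting individual ids.
    Homozygotes contribute node membership only — no self-edges.
    """

    graph: nx.Graph
    individual_map: dict[str, tuple[str, ...]]
    flagged: set[str] = field(default_factory=set)

    @property
    def haplotypes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def multiplicity(self, hap: str) -> int:
        return self.graph.nodes[hap]["multiplicity"]

    def edge_support(self, h1: str, h2: str) -> list[str]:
        return sorted(self.graph.edges[h1, h2]["individuals"])


@dataclass
class SpeciesPartition:
    """FFR delimitation: haplotype components and individual assignments."""

    ffr_haplotypes: dict[str, set[str]]
    individual_ffr: dict[str, str]
    n_species: int
    flagged: set[str] = field(default_factory=set)

    def members(self, ffr_id: str) -> list[str]:
        return sorted(
            ind for ind, f in self.individual_ffr.items() if f == ffr_id
        )

    def as_labels(self, individuals: list[str]) -> list[str]:
        return [self.individual_ffr[i] for i in individuals]


def _normalize(hap: str) -> str:
    return hap.replace("-", "")


def build_haploweb(
    phased: Mapping[str, tuple[str, ...]],
    flagged: set[str] | None = None,
) -> HaplowebGraph:
    """Build the co-occurrence graph from phased individuals.

    `phased` maps individual id to its one or two haplotype strings.
    Individuals that phasing could not resolve may be passed with their
    ambiguity-collapsed sequence as a single haplotype, listed in
    `flagged`; they join the graph like homozygotes and are reported
    separately downstream.
    """
    g = nx.Graph()
    individual_map: dict[str, tuple[str, ...]] = {}
    for ind, haps in sorted(phased.items()):
        if not 1 <= len(haps) <= 2:
            raise ValueError(f"{ind}: expected 1 or 2 haplotypes, got {len(haps)}")
        norm = tuple(_normalize(h) for h in haps)
        individual_map[ind] = norm
        for h in set(norm):
            if h not in g:
                g.add_node(h, multiplicity=0)
            g.nodes[h]["multiplicity"] += norm.count(h)
        distinct = set(norm)
        if len(distinct) == 2:
            h1, h2 = sorted(distinct)
            if not g.has_edge(h1, h2):
                g.add_edge(h1, h2, individuals=set())
            g.edges[h1, h2]["individuals"].add(ind)
    return HaplowebGraph(
        graph=g, individual_map=individual_map, flagged=set(flagged or ()),
    )


def delimit_ffrs(web: HaplowebGraph) -> SpeciesPartition:
    """Fields for recombination = connected components of the haploweb.

    Each individual is assigned to the component containing its
    haplotype(s); an individual whose two haplotypes fall in different
    components is impossible by construction (its own heterozygosity is an
    edge joining them) and triggers an assertion.
    """
    components = sorted(
        (sorted(c) for c in nx.connected_components(web.graph)),
        key=lambda c: c[0],
    )
    ffr_of_hap: dict[str, str] = {}
    ffr_haplotypes: dict[str, set[str]] = {}
    for k, comp in enumerate(components, start=1):
        fid = f"FFR{k:02d}"
        ffr_haplotypes[fid] = set(comp)
        for h in comp:
            ffr_of_hap[h] = fid
    individual_ffr: dict[str, str] = {}
    for ind, haps in web.individual_map.items():
        ffrs = {ffr_of_hap[h] for h in haps}
        assert len(ffrs) == 1, (
            f"{ind}: haplotypes span components {sorted(ffrs)} — "
            "impossible for a haploweb built from its own heterozygosity"
        )
        individual_ffr[ind] = next(iter(ffrs))
    populated = {f for f in individual_ffr.values()}
    return SpeciesPartition(
        ffr_haplotypes=ffr_haplotypes,
        individual_ffr=individual_ffr,
        n_species=len(populated),
        flagged=set(web.flagged),
    )


def partition_congruence(
    p1: SpeciesPartition,
    p2: SpeciesPartition | Mapping[str, str],
    tree: Tree | None = None,
) -> tuple[float, dict[str, bool]]:
    """Congruence of two delimitations of the same individuals.

    Returns the adjusted Rand index over the shared individuals and, when
    an independent-marker tree is supplied, whether each FFR of `p1` forms
    a clade (bipartition side) of that tree. Individuals absent from the
    tree are ignored in the monophyly check.
    """
    map1 = p1.individual_ffr
    map2 = p2.individual_ffr if isinstance(p2, SpeciesPartition) else dict(p2)
    shared = sorted(set(map1) & set(map2))
    if not shared:
        raise ValueError("partitions share no individuals")
    ari = float(
        adjusted_rand_score(
            [map1[i] for i in shared], [map2[i] for i in shared]
        )
    )
    monophyly: dict[str, bool] = {}
    if tree is not None:
        tips = tree.tips()
        for fid in sorted(set(map1.values())):
            members = frozenset(
                i for i, f in map1.items() if f == fid
            ) & tips
            if not members:
                continue
            monophyly[fid] = tree.has_group(members)
    return ari, monophyly


def plot_haploweb(
    web: HaplowebGraph,
    path: str | Path,
    partition: SpeciesPartition | None = None,
) -> None:
    """Plain plot of the co-occurrence graph, one colour per FFR.

    Node size scales with haplotype multiplicity; layout is a seeded
    spring embedding. Aesthetics are intentionally minimal.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if partition is None:
        partition = delimit_ffrs(web)
    ffr_ids = sorted(partition.ffr_haplotypes)
    cmap = plt.get_cmap("tab10")
    colour_of = {fid: cmap(i % 10) for i, fid in enumerate(ffr_ids)}
    node_colours = []
    for h in web.graph.nodes:
        fid = next(
            f for f, haps in partition.ffr_haplotypes.items() if h in haps
        )
        node_colours.append(colour_of[fid])
    sizes = [60 + 40 * web.multiplicity(h) for h in web.graph.nodes]
    pos = nx.spring_layout(web.graph, seed=0)
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx_edges(web.graph, pos, ax=ax, edge_color="grey")
    nx.draw_networkx_nodes(
        web.graph, pos, ax=ax, node_color=node_colours, node_size=sizes
    )
    ax.set_axis_off()
    ax.set_title(f"haploweb: {partition.n_species} fields for recombination")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_edge_list(web: HaplowebGraph, path: str | Path) -> None:
    lines = ["haplotype_1\thaplotype_2\tn_individuals\tindividuals"]
    for h1, h2, data in sorted(web.graph.edges(data=True)):
        inds = sorted(data["individuals"])
        lines.append(f"{h1}\t{h2}\t{len(inds)}\t{','.join(inds)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_species_table(part: SpeciesPartition, path: str | Path) -> None:
    lines = ["individual_id\tffr_id\tflag"]
    for ind in sorted(part.individual_ffr):
        flag = "unresolved_phase" if ind in part.flagged else "."
        lines.append(f"{ind}\t{part.individual_ffr[ind]}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")
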