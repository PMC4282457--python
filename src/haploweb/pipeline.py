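"""End-to-end orchestration: delimitation, epibiont screening, ecology.

The pipeline composes the stage modules in the order the analysis
requires: unravel length-variant heterozygotes from their mixed traces,
phase the remaining heterozygotes by Clark's method, build the ITS
haploweb and delimit fields for recombination, build the COI
neighbour-joining tree with bootstrap supports and report congruence;
then screen 16S queries against the labelled reference set, resolve
two-clade mixtures, tally screening outcomes, and classify sites into
sulphidic vs nonsulphidic with the Eh-based sulphide inference.

Every function is usable directly from Python on in-memory objects; the
file-based entry points (`run_delimitation`, `run_full_study`) read the
standard formats written by the synthetic generator or by the user.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import Align

from . import deconvolution as dec
from . import delimit as dl
from . import ecology as eco
from . import epibiont as epi
from . import njtree as njt
from . import phasing as ph
from .seq_core import Alignment, Marker, Sequence, distance_matrix, filter_codon_positions, read_fasta

__all__ = [
    "PipelineConfig",
    "RunReport",
    "deconvolve_trace_pair",
    "delimit_its",
    "coi_clusters",
    "run_delimitation",
    "run_full_study",
]

log = logging.getLogger("haploweb")


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for a pipeline run."""

    its_fasta: Path | str | None = None
    coi_fasta: Path | str | None = None
    trace_dir: Path | str | None = None
    site_table: Path | str | None = None
    screening_table: Path | str | None = None
    reference_fasta: Path | str | None = None
    reference_clades: Path | str | None = None
    queries_fasta: Path | str | None = None
    out_dir: Path | str = "haploweb_out"
    bootstrap: int = 1000
    max_delta: int = 3
    assign_threshold: float = 90.0
    margin_threshold: float = 1.0
    coi_cluster_threshold: float = 0.05
    seed: int = 0


@dataclass
class RunReport:
    """Aggregated per-stage results; serialisable to JSON."""

    n_individuals: int = 0
    n_length_variant: int = 0
    n_phased: int = 0
    n_unresolved: int = 0
    n_species: int = 0
    species_assignment: dict[str, str] = field(default_factory=dict)
    bootstrap_support: dict[str, float] = field(default_factory=dict)
    coi_ari: float | None = None
    coi_monophyly: dict[str, bool] = field(default_factory=dict)
    coi_newick: str | None = None
    habitat: dict[str, object] = field(default_factory=dict)
    screening: dict[str, int] = field(default_factory=dict)
    clade_table: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(type(o))

        return json.dumps(self.__dict__, indent=2, default=default, sort_keys=True)


# ---------------------------------------------------------------------------
# deconvolution + threading helpers


def deconvolve_trace_pair(
    fwd: dec.MixedTrace, rev: dec.MixedTrace, max_delta: int = 3
) -> dec.DeconvolutionResult:
    """Score candidate shifts and deconvolve at the best consistent shift.

    Candidate length differences are tried in decreasing score order
    (ties toward the smaller Δ); the first fully consistent solution
    wins. The result carries the uniqueness flag of the constraint
    solution itself.
    """
    scores = dec.score_shifts(fwd, rev, max_delta=max_delta)
    last: dec.DeconvolutionError | None = None
    for s in scores:
        try:
            return dec.deconvolve(fwd, rev, s.delta)
        except dec.DeconvolutionError as e:
            last = e
    raise last if last is not None else ValueError("no candidate shifts")


_threader = Align.PairwiseAligner()
_threader.mode = "global"
_threader.match_score = 1.0
_threader.mismatch_score = -1.0
_threader.open_gap_score = -4.0
_threader.extend_gap_score = -0.5
_threader.end_insertion_score = 0.0
_threader.end_deletion_score = 0.0


def _thread_into_alignment(seq: str, aligned_refs: list[str]) -> str | None:
    """Place an unaligned haplotype into alignment coordinates.

    The haplotype is globally aligned against the (degapped) closest
    reference haplotype and its residues transferred through the
    reference's gap pattern. Insertions relative to every reference
    cannot be represented and yield None.
    """
    best = None
    for ref_aligned in aligned_refs:
        ref = ref_aligned.replace("-", "")
        if not ref:
            continue
        score = _threader.score(ref, seq)
        if best is None or score > best[0]:
            best = (score, ref_aligned, ref)
    if best is None:
        return None
    _, ref_aligned, ref = best
    aln = _threader.align(ref, seq)[0]
    r_row, s_row = str(aln[0]), str(aln[1])
    colmap = [i for i, ch in enumerate(ref_aligned) if ch != "-"]
    out = ["-"] * len(ref_aligned)
    ri = 0
    for r_chr, s_chr in zip(r_row, s_row):
        if r_chr == "-":
            if s_chr != "-":
                return None  # insertion relative to the reference
            continue
        if s_chr != "-":
            out[colmap[ri]] = s_chr
        ri += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# ITS delimitation


@dataclass
class DelimitationResult:
    phase: ph.PhaseResult | None
    web: dl.HaplowebGraph
    partition: dl.SpeciesPartition
    haplotype_alignment: Alignment | None
    taxon_of_haplotype: dict[str, str]
    warnings: list[str]


def delimit_its(
    its: Alignment | None,
    traces: Mapping[str, tuple[dec.MixedTrace, dec.MixedTrace]] | None = None,
    max_delta: int = 3,
) -> DelimitationResult:
    """Phase, deconvolve, build the haploweb and delimit FFRs.

    Returns, besides the partition, an alignment of the distinct
    haplotypes (deconvolved length variants threaded back into alignment
    coordinates) for downstream tree building and bootstrap.
    """
    warnings: list[str] = []
    phased: dict[str, tuple[str, ...]] = {}
    aligned_of: dict[str, str] = {}  # normalized haplotype -> aligned string
    flagged: set[str] = set()

    phase_result = None
    if its is not None:
        genotypes = ph.genotypes_from_iupac(its)
        phase_result = ph.clark_phase(genotypes)
        for g in phase_result.genotypes:
            if g.resolved is None:
                collapsed = its[g.individual_id].residues
                phased[g.individual_id] = (collapsed,)
                flagged.add(g.individual_id)
                warnings.append(
                    f"{g.individual_id}: unresolved by Clark phasing; joined "
                    "haploweb as ambiguity-collapsed sequence"
                )
            else:
                phased[g.individual_id] = g.resolved
                for h in g.resolved:
                    aligned_of.setdefault(h.replace("-", ""), h)

    unaligned: dict[str, str] = {}
    for ind, (fwd, rev) in sorted((traces or {}).items()):
        try:
            res = deconvolve_trace_pair(fwd, rev, max_delta=max_delta)
        except (dec.DeconvolutionError, dec.NoLengthVariance, ValueError) as e:
            warnings.append(f"{ind}: trace deconvolution failed ({e})")
            continue
        if not res.unique:
            warnings.append(f"{ind}: deconvolution solution not unique; "
                            "deterministic representative used")
        pair = (res.haplotype_long.residues, res.haplotype_short.residues)
        phased[ind] = pair
        for h in pair:
            unaligned.setdefault(h, h)

    web = dl.build_haploweb(phased, flagged=flagged)
    partition = dl.delimit_ffrs(web)

    # thread deconvolved haplotypes into alignment coordinates for trees
    taxon_of: dict[str, str] = {}
    records: list[Sequence] = []
    aligned_pool = list(aligned_of.values())
    k = 0
    for hap in sorted(set(aligned_of) | set(unaligned)):
        k += 1
        tid = f"hap{k:03d}"
        taxon_of[hap] = tid
        if hap in aligned_of:
            records.append(Sequence(tid, aligned_of[hap], Marker.ITS))
        else:
            threaded = _thread_into_alignment(hap, aligned_pool)
            if threaded is None:
                warnings.append(
                    f"haplotype {tid}: could not be threaded into the "
                    "alignment; excluded from tree building"
                )
                taxon_of.pop(hap)
                k -= 1
                continue
            records.append(Sequence(tid, threaded, Marker.ITS))
    hap_aln = Alignment(records) if len(records) >= 1 and records else None
    return DelimitationResult(
        phase=phase_result,
        web=web,
        partition=partition,
        haplotype_alignment=hap_aln,
        taxon_of_haplotype=taxon_of,
        warnings=warnings,
    )


def ffr_taxon_groups(res: DelimitationResult) -> dict[str, frozenset[str]]:
    """Per-FFR sets of haplotype taxon ids present in the tree alignment."""
    groups: dict[str, frozenset[str]] = {}
    for fid, haps in res.partition.ffr_haplotypes.items():
        taxa = frozenset(
            res.taxon_of_haplotype[h] for h in haps if h in res.taxon_of_haplotype
        )
        if taxa:
            groups[fid] = taxa
    return groups


def coi_clusters(
    coi: Alignment, threshold: float = 0.05, codon_keep: tuple[int, ...] = (1, 2)
) -> dict[str, str]:
    """Single-linkage clusters of COI sequences at a K2P distance cutoff.

    1st+2nd codon positions only; serves as the mitochondrial partition
    against which the ITS delimitation is checked, not as a delimitation
    of its own.
    """
    import networkx as nx

    sub = filter_codon_positions(coi, frame=1, keep=set(codon_keep))
    dm = distance_matrix(sub)
    g = nx.Graph()
    g.add_nodes_from(dm.ids)
    n = len(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if dm.d[i, j] <= threshold:
                g.add_edge(dm.ids[i], dm.ids[j])
    out: dict[str, str] = {}
    for k, comp in enumerate(
        sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]),
        start=1,
    ):
        for ind in comp:
            out[ind] = f"mt{k:02d}"
    return out


# ---------------------------------------------------------------------------
# file-based runs


def _read_traces(trace_dir: Path) -> dict[str, tuple[dec.MixedTrace, dec.MixedTrace]]:
    traces: dict[str, tuple[dec.MixedTrace, dec.MixedTrace]] = {}
    for fwd_path in sorted(trace_dir.glob("*.fwd.trace")):
        ind = fwd_path.name[: -len(".fwd.trace")]
        rev_path = trace_dir / f"{ind}.rev.trace"
        if not rev_path.exists():
            raise FileNotFoundError(f"missing reverse trace for {ind}")
        traces[ind] = (dec.read_trace(fwd_path), dec.read_trace(rev_path))
    return traces


def _setup_run_log(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == out_dir / "run.log"
        for h in log.handlers
    ):
        handler = logging.FileHandler(out_dir / "run.log")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(logging.INFO)


def run_delimitation(cfg: PipelineConfig) -> RunReport:
    """Deconvolve, phase, delimit, tree and congruence-check from files."""
    out_dir = Path(cfg.out_dir)
    _setup_run_log(out_dir)
    report = RunReport()
    rng = np.random.default_rng(cfg.seed)

    its = read_fasta(cfg.its_fasta, Marker.ITS) if cfg.its_fasta else None
    traces = _read_traces(Path(cfg.trace_dir)) if cfg.trace_dir else {}
    if its is None and not traces:
        raise ValueError("delimitation needs an ITS FASTA and/or traces")
    log.info("[delimit] %d IUPAC genotypes, %d trace pairs",
             len(its) if its else 0, len(traces))

    res = delimit_its(its, traces, max_delta=cfg.max_delta)
    report.warnings.extend(res.warnings)
    report.n_individuals = len(res.partition.individual_ffr)
    report.n_length_variant = len(traces)
    report.n_unresolved = len(res.phase.unresolved_ids) if res.phase else 0
    report.n_phased = report.n_individuals - report.n_unresolved
    report.n_species = res.partition.n_species
    report.species_assignment = dict(res.partition.individual_ffr)
    dl.write_species_table(res.partition, out_dir / "species_assignment.tsv")
    dl.write_edge_list(res.web, out_dir / "haploweb_edges.tsv")
    dl.plot_haploweb(res.web, out_dir / "haploweb.png", res.partition)
    if res.phase is not None:
        ph.write_phase_report(res.phase, out_dir / "phase_report.tsv")
    log.info("[delimit] %d FFRs over %d individuals",
             report.n_species, report.n_individuals)

    if res.haplotype_alignment is not None and len(res.haplotype_alignment) >= 3:
        groups = ffr_taxon_groups(res)
        supports = njt.bootstrap_supports(
            res.haplotype_alignment,
            list(groups.values()),
            B=cfg.bootstrap,
            rng=rng,
        )
        report.bootstrap_support = {
            fid: supports[taxa] for fid, taxa in groups.items()
        }
        log.info("[tree] ITS bootstrap supports: %s", report.bootstrap_support)

    if cfg.coi_fasta and Path(cfg.coi_fasta).exists():
        coi = read_fasta(cfg.coi_fasta, Marker.COI)
        clusters = coi_clusters(coi, threshold=cfg.coi_cluster_threshold)
        sub = filter_codon_positions(coi, frame=1, keep={1, 2})
        tree = njt.build_nj_tree(distance_matrix(sub))
        report.coi_newick = tree.newick()
        (out_dir / "coi_tree.nwk").write_text(report.coi_newick + "\n")
        ari, mono = dl.partition_congruence(res.partition, clusters, tree=tree)
        report.coi_ari = ari
        report.coi_monophyly = mono
        log.info("[congruence] ARI vs COI clusters = %.3f", ari)
    else:
        report.warnings.append("COI input missing; congruence section skipped")
        log.info("[congruence] skipped (no COI input)")

    (out_dir / "report.json").write_text(report.to_json() + "\n")
    return report


def run_full_study(cfg: PipelineConfig) -> RunReport:
    """Delimitation + epibiont screening + ecology summary in one report."""
    out_dir = Path(cfg.out_dir)
    report = run_delimitation(cfg)

    # epibiont screening
    if cfg.reference_fasta and cfg.queries_fasta:
        refs_aln = read_fasta(cfg.reference_fasta, Marker.RRNA_16S)
        clade_map: dict[str, str] = {}
        if cfg.reference_clades:
            for ln in Path(cfg.reference_clades).read_text().splitlines()[1:]:
                if ln.strip():
                    rid, clade = ln.split("\t")[:2]
                    clade_map[rid] = clade
        refs = epi.ReferenceSet(sequences=refs_aln.sequences, clades=clade_map)
        queries = read_fasta(cfg.queries_fasta, Marker.RRNA_16S)
        assignments = [
            epi.assign_clade(
                q, refs,
                assign_threshold=cfg.assign_threshold,
                margin_threshold=cfg.margin_threshold,
            )
            for q in queries.sequences
        ]
        epi.write_clade_report(assignments, out_dir / "clade_assignments.tsv")
        report.clade_table = {
            a.query_id: (
                a.best_clade
                if a.status is epi.AssignmentStatus.ASSIGNED
                else a.status.value
            )
            for a in assignments
        }
        # mixtures, if present
        if cfg.trace_dir:
            for mix_path in sorted(Path(cfg.trace_dir).glob("*.mix.trace")):
                tr = dec.read_trace(mix_path)
                pair = epi.resolve_mixture_by_reference(tr, refs)
                if pair is None:
                    report.warnings.append(
                        f"{tr.id}: mixture unresolved against references"
                    )
                else:
                    c1, c2 = (refs.clades.get(p.id, "?") for p in pair)
                    report.clade_table[tr.id] = f"{min(c1, c2)}+{max(c1, c2)}"
        log.info("[epibiont] %d queries assigned", len(report.clade_table))
        # rarefaction over assigned-clade abundances
        counts = [
            sum(1 for v in report.clade_table.values() if v == c)
            for c in sorted(set(report.clade_table.values()))
        ]
        counts = [c for c in counts if c > 0]
        if counts and sum(counts) >= 2:
            pts = epi.rarefaction_curve(counts, step=1)
            epi.write_rarefaction_table(pts, out_dir / "rarefaction.tsv")

    # screening tally
    if cfg.screening_table and Path(cfg.screening_table).exists():
        records = eco.read_screening_table(cfg.screening_table)
        tally = eco.screening_tally(records)
        report.screening = {
            "thiothrix_positive": tally.thiothrix_positive,
            "other_bacteria": tally.other_bacteria,
            "negative": tally.negative,
            "total": tally.total,
        }
        if tally.total == 0:
            report.warnings.append("screening table empty; tally is all zeros")
        log.info("[screening] %s", report.screening)

    # ecology
    if cfg.site_table and Path(cfg.site_table).exists():
        sites = eco.read_site_table(cfg.site_table)
        summary = eco.species_habitat_tally(sites)
        report.habitat = {
            "sulphidic_species": sorted(summary.sulphidic_species),
            "nonsulphidic_only_species": sorted(summary.nonsulphidic_only_species),
            "n_sulphidic_species": len(summary.sulphidic_species),
            "n_nonsulphidic_only_species": len(summary.nonsulphidic_only_species),
            "n_species_total": len(summary.all_species),
        }
        try:
            model = eco.fit_eh_h2s(sites)
            report.habitat["eh_h2s_slope"] = model.slope
            report.habitat["eh_h2s_intercept"] = model.intercept
        except ValueError as e:
            report.warnings.append(f"Eh-H2S regression not fitted: {e}")
        log.info("[ecology] %s", report.habitat)

    (out_dir / "report.json").write_text(report.to_json() + "\n")
    return report
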