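"""Synthetic datasets with the statistical structure the pipeline assumes.

No machine-readable sequence data accompany the source survey, so the
generator emulates its data regime end to end: several deeply divergent
species each carrying a shallow pool of nuclear (ITS) alleles — some with
an indel, producing length-variant heterozygotes — and mitochondrial
(COI) haplotypes; diploid individuals drawing two ITS alleles from their
own species' pool only; bacterial 16S epibiont communities in which one
clade (T3) occurs in both habitat types while another (T4) occurs
exclusively at sulphidic sites; and site records with a quasi-linear
Eh–H2S relationship and zero sulphide at positive redox potential.

Mutations follow a Kimura two-parameter process with transition/
transversion ratio 2, matching the K2P distance used downstream. All
randomness flows from a single seeded generator, so observed data are a
deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .deconvolution import MixedTrace, simulate_superposition, write_trace
from .ecology import ScreeningRecord, SiteRecord, write_screening_table, write_site_table
from .epibiont import ReferenceSet
from .phasing import collapse_to_iupac
from .seq_core import Alignment, Marker, Sequence, write_fasta, write_species_map

__all__ = [
    "SimulationConfig",
    "Individual",
    "SyntheticDataset",
    "mutate",
    "random_sequence",
    "simulate_species_pools",
    "simulate_individuals",
    "simulate_sites",
    "build_reference_set",
    "simulate_epibiont_screening",
    "simulate_dataset",
    "simulate_study_screening",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": "CT", "G": "CT", "C": "AG", "T": "AG",
}

# forward-primer site is planted so that the THIO714F..THIO1492R amplicon
# is 778 bp, the span the published ~800 bp band corresponds to
_FWD_SITE_START = 714   # 1-based
_AMPLICON_LENGTH = 778


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Divergences are expected substitutions per site; the interspecific
    default is 30x the intraspecific one, reproducing the deep-split /
    shallow-variation regime under which the delimitation operates.
    """

    n_species: int = 5
    n_individuals: int = 8          # per species
    inter_divergence: float = 0.15
    intra_divergence: float = 0.005
    its_length: int = 500
    coi_length: int = 600
    rrna16s_length: int = 1500
    pool_size: int = 4              # alleles per species ITS/COI pool
    p_heterozygote: float = 0.5
    p_length_variant: float = 0.1   # per species pool
    indel_length: int = 3
    n_sites: int = 8
    p_sulphidic: float = 0.5
    eh_h2s_slope: float = -0.6      # μM per mV
    eh_h2s_intercept: float = 13.0  # μM
    h2s_noise_sd: float = 5.0       # μM
    p_h2s_inferred: float = 0.3
    # epibiont detection probabilities conditional on habitat
    p_t3_sulphidic: float = 0.35
    p_t3_nonsulphidic: float = 0.3
    p_t4_sulphidic: float = 0.35
    p_t4_nonsulphidic: float = 0.0
    p_other_bacteria: float = 0.15
    clade_divergence: float = 0.04
    within_clade_divergence: float = 0.008
    query_noise: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inter_divergence <= self.intra_divergence:
            raise ValueError(
                "interspecific divergence must exceed intraspecific divergence"
            )
        probs = (
            self.p_heterozygote, self.p_length_variant, self.p_sulphidic,
            self.p_t3_sulphidic, self.p_t3_nonsulphidic, self.p_t4_sulphidic,
            self.p_t4_nonsulphidic, self.p_other_bacteria, self.p_h2s_inferred,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(
    seq: str,
    divergence: float,
    rng: np.random.Generator,
    protected: tuple[tuple[int, int], ...] = (),
) -> str:
    """K2P substitution process: each site mutates with probability
    `divergence`; a mutation is a transition with probability 2/3 (ts/tv
    ratio 2), otherwise one of the two transversions. Gap characters and
    0-based [start, end) `protected` windows are left untouched."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < divergence)[0]
    for i in hits:
        base = out[i]
        if base == "-":
            continue
        if any(s <= i < e for s, e in protected):
            continue
        if rng.random() < 2.0 / 3.0:
            out[i] = _TRANSITION[base]
        else:
            out[i] = _TRANSVERSIONS[base][rng.integers(2)]
    return "".join(out)


@dataclass
class Individual:
    id: str
    species: str
    its_pair: tuple[str, str]      # aligned allele strings (may carry gaps)
    coi: str
    site_id: str | None = None
    is_length_variant: bool = False


@dataclass
class SyntheticDataset:
    """Planted truth plus the observed files every pipeline stage consumes."""

    config: SimulationConfig
    individuals: list[Individual]
    its_genotypes: Alignment               # IUPAC-collapsed, equal-length hets
    traces: dict[str, tuple[MixedTrace, MixedTrace]]  # length-variant hets
    coi: Alignment
    sites: list[SiteRecord]
    screening: list[ScreeningRecord]
    queries: list[Sequence]                # 16S screening sequences
    query_clades: dict[str, str]           # planted clade per query id
    mixture_traces: dict[str, MixedTrace]  # two-clade mixtures
    mixture_pairs: dict[str, tuple[str, str]]
    references: ReferenceSet
    species_of: dict[str, str] = field(default_factory=dict)

    def write_to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.its_genotypes.sequences, outdir / "its_genotypes.fasta")
        write_fasta(self.coi.sequences, outdir / "coi.fasta")
        tdir = outdir / "traces"
        tdir.mkdir(exist_ok=True)
        for ind, (fwd, rev) in self.traces.items():
            write_trace(fwd, tdir / f"{ind}.fwd.trace")
            write_trace(rev, tdir / f"{ind}.rev.trace")
        for qid, tr in self.mixture_traces.items():
            write_trace(tr, tdir / f"{qid}.mix.trace")
        write_site_table(self.sites, outdir / "sites.tsv")
        write_screening_table(self.screening, outdir / "screening.tsv")
        write_fasta(self.queries, outdir / "queries_16s.fasta")
        write_fasta(self.references.sequences, outdir / "references_16s.fasta")
        clade_lines = ["reference_id\tclade"]
        clade_lines += [
            f"{rid}\t{clade}"
            for rid, clade in sorted(self.references.clades.items())
        ]
        (outdir / "reference_clades.tsv").write_text("\n".join(clade_lines) + "\n")
        write_species_map(self.species_of, outdir / "truth_species_map.tsv")


# ---------------------------------------------------------------------------
# host side


def simulate_species_pools(
    cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, dict[str, list[str]]]:
    """Per-species ITS allele pools and COI haplotype pools.

    Species ancestors are mutated from a common root at the interspecific
    divergence; within-species alleles at the intraspecific divergence.
    With probability p_length_variant a pool gains one allele carrying an
    indel (represented by gap characters, so pools stay aligned).
    """
    its_root = random_sequence(cfg.its_length, rng)
    coi_root = random_sequence(cfg.coi_length, rng)
    pools: dict[str, dict[str, list[str]]] = {}
    for k in range(1, cfg.n_species + 1):
        name = f"sp{k:02d}"
        its_anc = mutate(its_root, cfg.inter_divergence, rng)
        coi_anc = mutate(coi_root, cfg.inter_divergence, rng)
        its_pool = [
            mutate(its_anc, cfg.intra_divergence, rng)
            for _ in range(cfg.pool_size)
        ]
        if cfg.indel_length > 0 and rng.random() < cfg.p_length_variant:
            # one aligned length-variant allele per pool: a clean deletion
            i = int(rng.integers(1, cfg.pool_size))
            pos = int(rng.integers(10, cfg.its_length - cfg.indel_length - 10))
            a = its_pool[i]
            its_pool[i] = a[:pos] + "-" * cfg.indel_length + a[pos + cfg.indel_length:]
        coi_pool = [
            mutate(coi_anc, cfg.intra_divergence, rng)
            for _ in range(cfg.pool_size)
        ]
        pools[name] = {"ITS": its_pool, "COI": coi_pool}
    return pools


def simulate_individuals(
    pools: Mapping[str, Mapping[str, list[str]]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[Individual], Alignment, dict[str, tuple[MixedTrace, MixedTrace]], Alignment]:
    """Diploid hosts: two ITS alleles from the own-species pool, one COI.

    Sampling emulates the regime in which Clark phasing plus haploweb
    delimitation is exact: within each species every realized allele is
    observed in at least one homozygote (Clark's anchoring condition) and
    the realized alleles are linked through heterozygous individuals (the
    first heterozygotes carry a spanning chain of allele pairs; further
    heterozygotes draw random pairs), so the species' haplotypes form one
    field for recombination. The realized-pool size is therefore limited
    by both the number of heterozygotes (chaining) and the number of
    homozygotes (anchoring) — shallow sampling realizes fewer alleles,
    as in real surveys. Equal-length heterozygotes are emitted as
    IUPAC-collapsed sequences; length-variant heterozygotes as
    forward+reverse mixed traces.
    """
    individuals: list[Individual] = []
    its_records: list[Sequence] = []
    coi_records: list[Sequence] = []
    traces: dict[str, tuple[MixedTrace, MixedTrace]] = {}
    for species in sorted(pools):
        its_pool = pools[species]["ITS"]
        coi_pool = pools[species]["COI"]
        het = rng.random(cfg.n_individuals) < cfg.p_heterozygote
        if het.all() and cfg.n_individuals > 0:
            het[0] = False  # at least one homozygous anchor per species
        n_het = int(het.sum())
        n_hom = cfg.n_individuals - n_het
        # realized alleles: chainable by hets, each anchored by a hom
        m = max(1, min(len(its_pool), n_het + 1, n_hom))
        chain_i = 0
        hom_cover = list(rng.permutation(m))
        for j in range(1, cfg.n_individuals + 1):
            ind_id = f"{species}_i{j:02d}"
            if het[j - 1] and m >= 2:
                if chain_i < m - 1:
                    i1, i2 = chain_i, chain_i + 1
                    chain_i += 1
                else:
                    i1, i2 = rng.choice(m, size=2, replace=False)
                pair = (its_pool[int(i1)], its_pool[int(i2)])
            else:
                if hom_cover:
                    a = its_pool[int(hom_cover.pop())]
                else:
                    a = its_pool[int(rng.integers(m))]
                pair = (a, a)
            coi = coi_pool[int(rng.integers(len(coi_pool)))]
            lv = len(pair[0].replace("-", "")) != len(pair[1].replace("-", ""))
            ind = Individual(
                id=ind_id, species=species, its_pair=pair, coi=coi,
                is_length_variant=lv,
            )
            individuals.append(ind)
            coi_records.append(Sequence(ind_id, coi, Marker.COI))
            if lv:
                x = Sequence(ind_id, pair[0].replace("-", ""), Marker.ITS)
                y = Sequence(ind_id, pair[1].replace("-", ""), Marker.ITS)
                traces[ind_id] = simulate_superposition(x, y)
            else:
                its_records.append(
                    Sequence(
                        ind_id, collapse_to_iupac(pair[0], pair[1]), Marker.ITS
                    )
                )
    return (
        individuals,
        Alignment(its_records) if its_records else None,  # type: ignore[return-value]
        traces,
        Alignment(coi_records),
    )


def simulate_sites(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    individuals: list[Individual] | None = None,
) -> list[SiteRecord]:
    """Site records in the quasi-linear Eh–H2S regime.

    Sulphidic sites draw Eh in the reduced range with
    H2S = slope*Eh + intercept + noise; nonsulphidic sites draw positive
    Eh with H2S = 0. At least two sulphidic sites carry directly measured
    H2S so the regression stays fittable. When hosts are supplied they
    are assigned to sites round-robin per species, and each site's
    species list is derived from its hosts.
    """
    n_sulph = max(2, int(round(cfg.p_sulphidic * cfg.n_sites)))
    n_sulph = min(n_sulph, cfg.n_sites - 1) if cfg.n_sites > 2 else n_sulph
    records: list[SiteRecord] = []
    specs: list[tuple[str, bool]] = []
    for k in range(cfg.n_sites):
        specs.append((f"site{k + 1:02d}", k < n_sulph))
    site_species: dict[str, set[str]] = {s: set() for s, _ in specs}
    if individuals:
        sulph_ids = [s for s, is_s in specs if is_s]
        nonsulph_ids = [s for s, is_s in specs if not is_s]
        # species spread across both habitat types at random
        for i, ind in enumerate(individuals):
            pool = sulph_ids if rng.random() < cfg.p_sulphidic else nonsulph_ids
            ind.site_id = pool[int(rng.integers(len(pool)))]
            site_species[ind.site_id].add(ind.species)
    for k, (sid, is_sulph) in enumerate(specs):
        if is_sulph:
            eh = round(float(rng.uniform(-350.0, -60.0)), 1)
            h2s = cfg.eh_h2s_slope * eh + cfg.eh_h2s_intercept
            inferred = rng.random() < cfg.p_h2s_inferred and k >= 2
            if not inferred:
                h2s += float(rng.normal(0.0, cfg.h2s_noise_sd))
            h2s = max(h2s, 1.0)
        else:
            eh = round(float(rng.uniform(20.0, 140.0)), 1)
            h2s = 0.0
            inferred = rng.random() < cfg.p_h2s_inferred
        species = site_species[sid] or {"unsampled"}
        records.append(
            SiteRecord(
                town="synthetic", location=sid, latitude=".", longitude=".",
                date="01.2020", temp_c=float(rng.uniform(13.0, 21.0)),
                ec_us_cm=float(rng.uniform(1000.0, 2500.0)), eh_mv=eh,
                h2s_um=h2s, h2s_inferred=inferred,
                species=frozenset(species),
            )
        )
    return records


# ---------------------------------------------------------------------------
# epibiont side


def build_reference_set(
    cfg: SimulationConfig, rng: np.random.Generator, n_per_clade: int = 2
) -> ReferenceSet:
    """Synthetic labelled 16S reference set (clades T1–T4 and mat).

    Stand-in reference sequences generated from a common root; primer
    sites for the packaged forward/reverse primer pair are planted so the
    predicted amplicon is 778 bp, and are protected from mutation within
    Thiothrix clades. Users may substitute a real labelled FASTA.
    """
    from .epibiont import packaged_oligos

    oligos = packaged_oligos()
    fwd, rev = oligos["THIO714F"], oligos["THIO1492R"]
    root = list(random_sequence(cfg.rrna16s_length, rng))
    fstart = _FWD_SITE_START - 1
    root[fstart:fstart + len(fwd)] = fwd.bases
    rend = fstart + _AMPLICON_LENGTH  # 0-based exclusive end of reverse site
    rc = rev.bases.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    root[rend - len(rev):rend] = rc
    root_s = "".join(root)
    protected = ((fstart, fstart + len(fwd)), (rend - len(rev), rend))
    seqs: list[Sequence] = []
    clades: dict[str, str] = {}
    for clade in ("T1", "T2", "T3", "T4", "mat"):
        anc = mutate(root_s, cfg.clade_divergence, rng, protected=protected)
        for i in range(1, n_per_clade + 1):
            rid = f"{clade}_ref{i}"
            seqs.append(
                Sequence(
                    rid,
                    mutate(anc, cfg.within_clade_divergence, rng, protected=protected),
                    Marker.RRNA_16S,
                )
            )
            clades[rid] = clade
    return ReferenceSet(sequences=seqs, clades=clades)


def simulate_epibiont_screening(
    cfg: SimulationConfig,
    individuals: list[Individual],
    sites: list[SiteRecord],
    refs: ReferenceSet,
    rng: np.random.Generator,
) -> tuple[
    list[ScreeningRecord],
    list[Sequence],
    dict[str, str],
    dict[str, MixedTrace],
    dict[str, tuple[str, str]],
]:
    """16S queries and a screening table mirroring the habitat pattern.

    Clade T4 sequences are emitted only for hosts at sulphidic sites (a
    hard constraint when p_t4_nonsulphidic = 0); T3 for hosts at any
    site. Hosts detected with both clades emit a two-clade mixture trace
    instead of a clean query. Remaining hosts are other-bacteria or
    negative.
    """
    sulphidic = {s.location: s.h2s_um > 0 for s in sites}
    records: list[ScreeningRecord] = []
    queries: list[Sequence] = []
    query_clades: dict[str, str] = {}
    mixture_traces: dict[str, MixedTrace] = {}
    mixture_pairs: dict[str, tuple[str, str]] = {}

    def _query_from(clade: str, qid: str) -> Sequence:
        pool = refs.of_clade(clade)
        ref = pool[int(rng.integers(len(pool)))]
        return Sequence(qid, mutate(ref.residues, cfg.query_noise, rng), Marker.RRNA_16S)

    for ind in individuals:
        if ind.site_id is None:
            raise ValueError(f"{ind.id}: host not assigned to a site")
        is_sulph = sulphidic[ind.site_id]
        p_t3 = cfg.p_t3_sulphidic if is_sulph else cfg.p_t3_nonsulphidic
        p_t4 = cfg.p_t4_sulphidic if is_sulph else cfg.p_t4_nonsulphidic
        has_t3 = rng.random() < p_t3
        has_t4 = rng.random() < p_t4
        qid = f"{ind.id}_16S"
        if has_t3 and has_t4:
            t3pool = refs.of_clade("T3")
            t4pool = refs.of_clade("T4")
            r3 = t3pool[int(rng.integers(len(t3pool)))]
            r4 = t4pool[int(rng.integers(len(t4pool)))]
            pos = tuple(
                frozenset({a, b}) for a, b in zip(r3.residues, r4.residues)
            )
            from .deconvolution import Orientation

            mixture_traces[qid] = MixedTrace(
                id=qid, positions=pos, orientation=Orientation.FORWARD
            )
            mixture_pairs[qid] = (r3.id, r4.id)
            outcome, clade = "thiothrix", "T3+T4"
        elif has_t4:
            queries.append(_query_from("T4", qid))
            query_clades[qid] = "T4"
            outcome, clade = "thiothrix", "T4"
        elif has_t3:
            queries.append(_query_from("T3", qid))
            query_clades[qid] = "T3"
            outcome, clade = "thiothrix", "T3"
        elif rng.random() < cfg.p_other_bacteria:
            seq = mutate(refs.sequences[0].residues, 0.25, rng)
            queries.append(Sequence(qid, seq, Marker.RRNA_16S))
            query_clades[qid] = "other"
            outcome, clade = "other_bacteria", "other"
        else:
            outcome, clade = "negative", "."
        records.append(
            ScreeningRecord(
                specimen_id=ind.id, site_id=ind.site_id, species=ind.species,
                outcome=outcome, clade=clade,
            )
        )
    return records, queries, query_clades, mixture_traces, mixture_pairs


# ---------------------------------------------------------------------------
# whole datasets


def simulate_dataset(cfg: SimulationConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """One complete synthetic study: hosts, sites, epibionts, truth."""
    if cfg is None:
        cfg = SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    pools = simulate_species_pools(cfg, rng)
    individuals, its, traces, coi = simulate_individuals(pools, cfg, rng)
    sites = simulate_sites(cfg, rng, individuals)
    refs = build_reference_set(cfg, rng)
    screening, queries, query_clades, mix_traces, mix_pairs = (
        simulate_epibiont_screening(cfg, individuals, sites, refs, rng)
    )
    return SyntheticDataset(
        config=cfg,
        individuals=individuals,
        its_genotypes=its,
        traces=traces,
        coi=coi,
        sites=sites,
        screening=screening,
        queries=queries,
        query_clades=query_clades,
        mixture_traces=mix_traces,
        mixture_pairs=mix_pairs,
        references=refs,
        species_of={i.id: i.species for i in individuals},
    )


def simulate_study_screening(
    seed: int = 0,
    n_thiothrix: int = 21,
    n_other: int = 11,
    n_negative: int = 39,
) -> list[ScreeningRecord]:
    """A screening cohort with exact planted outcome counts.

    Defaults plant the source study's printed tallies: 21 of 71 DNA
    extracts Thiothrix-positive, 11 yielding bacteria other than
    Thiothrix, the remaining 39 negative. Specimen order is shuffled so
    the tally, not the layout, carries the signal.
    """
    rng = np.random.default_rng(seed)
    outcomes = (
        ["thiothrix"] * n_thiothrix
        + ["other_bacteria"] * n_other
        + ["negative"] * n_negative
    )
    rng.shuffle(outcomes)
    records = []
    for i, outcome in enumerate(outcomes, start=1):
        clade = "."
        if outcome == "thiothrix":
            clade = "T4" if rng.random() < 0.4 else "T3"
        elif outcome == "other_bacteria":
            clade = "other"
        records.append(
            ScreeningRecord(
                specimen_id=f"spec{i:03d}",
                site_id=f"site{int(rng.integers(1, 9)):02d}",
                species=f"sp{int(rng.integers(1, 8)):02d}",
                outcome=outcome,
                clade=clade,
            )
        )
    return records
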