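# Methods

This note documents the models, algorithms and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the limits of what the test suite demonstrates.

## Sequence model and distances

Sequences live over {A,C,G,T,-,N} plus the six two-fold IUPAC ambiguity
codes that direct Sanger sequencing of a diploid marker produces at
heterozygous positions. Distances are Kimura 2-parameter,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with P and Q the transition and transversion proportions over the sites
both sequences have a plain base at (pairwise deletion). IUPAC codes are
treated as missing in distance computation: a heterozygous position carries
no single-haplotype state, so counting it either way would bias P and Q.
When 1−2P−Q ≤ 0 or 1−2Q ≤ 0 the distance is undefined (saturated); it is
stored as +inf and flagged rather than raised, so a caller building a tree
gets an error naming the offending pair instead of a silent NaN. The
implementation was spot-checked against `ape::dist.dna(model="K80")`.

Two column filters are shared by the stages: a codon-position filter (for
protein-coding markers only 1st and 2nd positions enter the distance, the
3rd being saturated at these depths) and a consensus filter for rRNA
alignments. The consensus rule had to be fixed here: a column is retained
iff its modal character — gaps counted as characters — reaches the
threshold (default 50%) of all sequences. This is the simplest testable
reading of the common "soft filter"; treatments of gaps differ between
tools and are documented nowhere authoritative.

Column coordinates are 1-based everywhere a user sees them.

## Length-variant heterozygote deconvolution

A diploid with alleles X (length L) and Y (length L−Δ, Δ ≥ 1) sequenced
directly gives two superposed reads: the forward read imposes
{X[i], Y[i]} = F[i] (5′-aligned; the last Δ positions contain X only), the
reverse read, re-complemented into forward coordinates at parse time,
imposes {X[i], Y[i−Δ]} = R[i] (3′-aligned; the first Δ positions contain X
only). Strand handling is confined to I/O so the solver works in one
coordinate system.

Candidate Δ values are ranked by counting positions whose constraints are
mutually satisfiable. Comparing F[i] with R[i] is vacuous — both always
contain X[i] — so the score uses the short haplotype, which appears at
forward position i and reverse position i+Δ: positions with
F[i] ∩ R[i+Δ] ≠ ∅ (i < L−Δ) or |F[i]| = 1 (forward tail) count. A clean
two-haplotype superposition scores the full trace length at the true Δ and
generically less elsewhere. Double-peak and singleton agreements carry
equal weight; nothing in the observable behaviour of published tools pins
down a different weighting.

Given Δ, each doubleton constraint determines one member of the pair from
the other, so values propagate along chains seeded at singleton positions
(deterministic left-to-right order). Chains never reached by an anchor are
symmetric between the two haplotypes; a deterministic representative
(smallest base at the leftmost free position) is returned and the result
flagged non-unique. A contradiction reports the first offending position.
Equal-length all-singleton reads are reported as "no length variance"; an
equal-length read pair with double peaks is resolved at Δ = 0 into a
deterministic representative flagged non-unique, since no anchor can break
the symmetry — true phase resolution of such mixtures belongs to the
phasing stage. The solver is tested for exact equivalence against an
exhaustive enumeration oracle for lengths ≤ 12.

## Clark parsimony phasing

Equal-length heterozygotes are phased by Clark's method: seed the known
pool with the haplotypes of full homozygotes and of single-site
heterozygotes (whose phase is free), then repeatedly resolve any genotype
compatible with a known haplotype, adding the complement to the pool, to a
fixpoint. The method is order-dependent and the original publications fix
no order, so this implementation does: genotypes are visited in (ascending
heterozygosity, then id) order, and among multiple compatible resolutions
it prefers, in this order, (1) a resolution whose complement is itself
already known — i.e. one introducing no new haplotype, the parsimony at
the heart of the method — then (2) the known haplotype with the highest
current usage, then (3) lexicographic order. Preference (1) matters in
practice: a haplotype identical to the within-species consensus is
site-compatible with almost every genotype of its species, and a
usage-only rule happily pairs it with a chimeric "novel" complement even
when both true haplotypes are already in the pool. Individuals resolvable
in more than one way are resolved but flagged ambiguous; unresolvable ones
are reported and enter the haploweb as their ambiguity-collapsed sequence,
flagged, so the partition stays total while marking uncertainty.

Clark phasing is exact only when sampling anchors it: recovery of planted
phases is guaranteed (and tested) in the regime where every realized
haplotype occurs in at least one homozygote.

## Haploweb and FFR delimitation

Phased individuals induce a co-occurrence graph: one node per distinct
haplotype (gap characters stripped before comparison; no distance
threshold merges near-identical haplotypes, since the haploweb criterion is
co-occurrence, not similarity), one edge per heterozygote. Homozygotes
contribute node membership, not self-edges. Fields for recombination are
the connected components; each individual maps to exactly one FFR (its own
heterozygosity is an edge joining its two haplotypes — violation is an
assertion, not an error path). Congruence with a second partition is an
adjusted Rand index over shared individuals; against a tree, each FFR is
additionally checked for being one side of a bipartition. Conflicts are
reported, never auto-merged: no published reconciliation rule exists.

## Trees and bootstrap

Neighbour joining follows the classic Studier–Keppler agglomeration with a
deterministic smallest-index tie-break. Negative branch-length estimates
are clamped to zero with the deficit moved to the sister branch, keeping
the joined pair's path length; the final join is clamped plainly. Topology
is tested against scikit-bio's NJ on random additive matrices (where both
must recover the generating tree exactly). Bootstrap supports resample
columns with replacement, rebuild the tree, and count the replicates in
which a group is one side of a bipartition; singleton groups and the full
taxon set are trivially supported. The distance kernel is vectorised so a
hundred replicates on a few dozen haplotypes take milliseconds. The
mitochondrial partition used for congruence is single-linkage clustering
of COI sequences (1st+2nd codon positions) at a configurable K2P cutoff,
default 0.05 — between the intra- (≤0.01) and interspecific (≥0.1) ranges
this analysis presumes; it stands in for delimitation done by eye on a
haplotree and is reported as a comparison partition, not a delimitation of
its own.

## Epibiont screening

Primer/probe matching is ungapped sliding comparison; reverse primers scan
the plus strand for their reverse complement, reporting their binding
site's coordinates on the template. An amplicon spans the forward site's
5′ end to the reverse primer's 5′ end on the opposite strand, inclusive;
orientation-inconsistent pairs are rejected and multiple products are
returned sorted by length.

Clade assignment replaces a public-database BLAST with percent identity
against a packaged, user-extensible labelled reference set, preserving the
top-hit decision rule without a network dependence. Identity of pre-aligned
(equal-length) pairs is column-wise over mutually ungapped columns;
unaligned pairs are globally aligned end-gap-free (match 1, mismatch 0,
open −1, extend −0.5) and identity taken over aligned ungapped columns.
Defaults: assignment threshold 90% identity, ambiguity margin 1 percentage
point over the best other clade. Both are exposed; no published cutoffs
exist, and what made two clades "indistinguishable" in surveys is exactly
this kind of margin judgement, so the rule is explicit here.

Two-sequence mixtures with a reference library are resolved by exhaustive
pair search: the unique pair of references whose superposition reproduces
every base-set, else failure with the smallest violation count seen.

Rarefaction is the hypergeometric expectation
E[S_n] = Σᵢ(1 − C(N−Nᵢ,n)/C(N,n)), evaluated in log-gamma space; it is
tested against exhaustive enumeration (N ≤ 8) and Monte-Carlo subsampling
(within 3 SE).

## Site geochemistry

The packaged site table is typed verbatim from the source survey's
location/geochemistry table, including its duplicated row, which the
parser preserves and flags — fidelity over tidiness. H₂S inference fits
OLS of measured H₂S on Eh using only sites with directly measured,
strictly positive sulphide (slope −0.605 µM/mV, intercept 13.2 µM on the
packaged table). Measured zeros are excluded because the quasi-linear
relation visibly breaks at positive Eh; predictions are clamped at zero
there instead. This reconstruction reproduces all four printed inferred
values within 9% and clamps all five positive-Eh rows to exactly 0; the
published table states no fitting procedure, so ±20% is the claim the
tests make. "Sulphidic" means strictly H₂S > 0; a species occurring at
one or more sulphidic sites — occasionally or exclusively — counts as
sulphidic, the rest as restricted to nonsulphidic habitat.

## Synthetic data: what it emulates, what it does not

The generator plants: a root sequence per marker; species ancestors at the
interspecific divergence (default 0.15 subs/site) and within-species
alleles at the intraspecific divergence (default 0.005), K2P mutation
process with transition/transversion ratio 2 for consistency with the
distance; per species, a pool of 4 ITS alleles (optionally one carrying a
3-bp deletion, held as gap characters so pools stay aligned) and 4 COI
haplotypes; 5 species × 8 diploid individuals by default; sites in the
quasi-linear Eh–H₂S regime (slope −0.6, intercept 13, Gaussian noise sd
5 µM, zero sulphide at positive Eh); synthetic 16S references for clades
T1–T4 and mat with the published primer sites planted so the predicted
amplicon is 778 bp (the coordinate span the ~800 bp gel band corresponds
to); and habitat-conditional epibiont detection with
p(T4 | nonsulphidic) = 0 as a hard constraint and T3 present in both
habitat types.

Host sampling is deliberately placed in the regime where the method is
exact, because that is what the recovery tests assert: within each
species, every realized allele occurs in at least one homozygote (Clark's
anchoring condition) and the realized alleles are linked through
heterozygotes (the first heterozygotes carry a spanning chain of allele
pairs; the rest draw random pairs). Shallower sampling realizes fewer
alleles rather than violating the regime. Real surveys do not guarantee
this: alleles seen only in unanchored multi-site heterozygotes can be
mis-phased or split off as their own FFR, and the pipeline then reports
flags and warnings rather than silently merging. Passing recovery tests
therefore demonstrate correctness of the machinery under the method's
stated assumptions, not robustness of haploweb delimitation to sparse
sampling. The generator also omits: recombination within markers,
alignment error (inputs are pre-aligned by construction), sequencing
noise in base-set calls, chimeras, and within-individual epibiont
abundance structure.

All randomness flows from one seeded generator; observed data are a
deterministic function of (config, seed).

## Problem sizes and tolerances

The test suite and the acceptance script use: 500 random pairs (lengths
≤ 12, Δ ≤ 3) for deconvolution-vs-oracle equivalence; 20 seeded studies
(~790 individuals) for phasing recovery; 100 seeded studies for
delimitation (ARI, species count) with bootstrap B = 100 per study — the
operation's default stays B = 1000, and at the planted divergences support
is saturated well below either; 100 seeded studies (~1900 assignments)
for T4 habitat exclusivity; 10⁴ Monte-Carlo draws (3 SE) for rarefaction.
The Eh→H₂S reconstruction is asserted at ±20% against printed values, the
single-column bootstrap check at ±8 percentage points around the
1−(1−1/L)^L limit.

## Known limitations

- Clark phasing inherits its classic failure modes outside the anchored
  regime; the flags (`ambiguous`, `unresolved`) are the mitigation, not a
  cure.
- Deconvolution assumes clean base-set calls; it does not model peak-height
  noise or dropout, and traces are expected in matched forward/reverse
  pairs of equal superposition length.
- The NJ/bootstrap stage is the only support measure; likelihood and
  parsimony analyses are out of scope.
- Clade assignment is only as good as the reference set; the packaged one
  is synthetic (generated stand-ins, labelled as such) and intended to be
  replaced by real labelled accessions for real data.
- The mitochondrial comparison partition depends on a distance cutoff;
  it is a congruence check, not an independent delimitation method.
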