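"""Screen 16S sequences for Thiothrix epibionts.

Builds a synthetic labelled reference set, predicts the PCR product of
the packaged Thiothrix-specific primer pair, assigns simulated host
queries to epibiont clades by percent identity, resolves a two-clade
mixture against the references, and prints a rarefaction curve for the
assigned-clade abundances.
"""

import numpy as np

from haploweb.epibiont import (
    assign_clade,
    packaged_oligos,
    predict_amplicon,
    rarefaction_curve,
    resolve_mixture_by_reference,
)
from haploweb.simulate import simulate_dataset

ds = simulate_dataset(seed=3)
oligos = packaged_oligos()
print("packaged oligos:", ", ".join(oligos))

(amp,) = predict_amplicon(
    oligos["THIO714F"], oligos["THIO1492R"], ds.references.sequences[0], 0
)
print(f"predicted amplicon: {amp.length} bp "
      f"(positions {amp.start}-{amp.end}; gel band prints as ~800 bp)")

print(f"\nclade assignment of {len(ds.queries)} host 16S queries:")
tally: dict[str, int] = {}
for q in ds.queries:
    a = assign_clade(q, ds.references)
    label = a.best_clade if a.status.value == "assigned" else a.status.value
    tally[label] = tally.get(label, 0) + 1
for label, n in sorted(tally.items()):
    print(f"  {label:<14} {n}")

if ds.mixture_traces:
    qid, trace = next(iter(ds.mixture_traces.items()))
    pair = resolve_mixture_by_reference(trace, ds.references)
    clades = sorted(ds.references.clades[p.id] for p in pair)
    print(f"\nmixture {qid}: resolved against references as {'+'.join(clades)}")

counts = [n for label, n in sorted(tally.items()) if label not in ("non_thiothrix",)]
print("\nrarefaction of assigned clades (subsample size -> expected clades):")
for p in rarefaction_curve(counts, step=max(1, sum(counts) // 6)):
    print(f"  n={p.n:3d} -> {p.expected_otus:.2f}")
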