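"""Unravel a length-variant heterozygote from its two sequencing reads.

A diploid individual carries two alleles differing by a 1-bp indel;
direct sequencing superposes them, giving frame-shifted double peaks.
The forward and reverse reads constrain the two haplotypes enough to
recover both exactly.
"""

from haploweb.deconvolution import deconvolve, score_shifts, simulate_superposition
from haploweb.seq_core import Sequence

x = Sequence("allele_long", "ACGTACGT")
y = Sequence("allele_short", "ACGACGT")
fwd, rev = simulate_superposition(x, y)

print("forward superposition (5'-aligned):",
      " ".join("/".join(sorted(s)) for s in fwd.positions))
print("reverse superposition (3'-aligned):",
      " ".join("/".join(sorted(s)) for s in rev.positions))

scores = score_shifts(fwd, rev, max_delta=3)
print("\ncandidate length differences, best first:")
for s in scores:
    print(f"  delta={s.delta}: {s.score}/{len(fwd)} positions satisfiable")

res = deconvolve(fwd, rev, scores[0].delta)
print(f"\nresolved pair (unique={res.unique}):")
print("  long :", res.haplotype_long.residues)
print("  short:", res.haplotype_short.residues)
print("the planted alleles are recovered exactly; a non-unique solution "
      "would be flagged instead")
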