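"""Classify survey sites and species by sulphide regime.

Loads the packaged groundwater site table, fits the quasi-linear Eh-H2S
relationship on the sites with directly measured sulphide, infers H2S
where only redox potential was measured (clamping to zero in the
oxidized regime) and tallies species by habitat.
"""

from haploweb.ecology import (
    fit_eh_h2s,
    infer_h2s,
    packaged_site_table,
    species_habitat_tally,
)

sites = packaged_site_table()
print(f"site records: {len(sites)} "
      f"({sum(1 for s in sites if s.duplicate_of)} flagged duplicate)")

model = fit_eh_h2s(sites)
print(f"\nEh->H2S regression on {model.n_sites} measured sulphidic sites:")
print(f"  H2S[uM] = {model.slope:.3f} * Eh[mV] + {model.intercept:.1f}"
      f"   (r = {model.r_value:.3f})")

print("\ninferred sulphide where only Eh was measured:")
for s in sites:
    if s.h2s_inferred:
        pred = infer_h2s(model, s.eh_mv)
        print(f"  {s.location:<30} Eh {s.eh_mv:7.1f} mV -> {pred:6.1f} uM "
              f"(table prints {s.h2s_um:g})")

summary = species_habitat_tally(sites)
print(f"\nspecies at sulphidic sites ({len(summary.sulphidic_species)}): "
      + ", ".join(sorted(summary.sulphidic_species)))
print(f"restricted to nonsulphidic sites ({len(summary.nonsulphidic_only_species)}): "
      + ", ".join(sorted(summary.nonsulphidic_only_species)))
print(f"total species: {len(summary.all_species)}")
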