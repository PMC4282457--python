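# Thiothrix-specific primers and probes (5'->3', as published).
# THIO714F amplifies but sequences poorly; THIO718Fseq is the sequencing
# alternative. G123T is the Thiothrix FISH probe; G123T-C its one-base
# competitor that sharpens specificity.
THIO714F:
  bases: ATG CAT AGA GAT CGG AAG G
  role: forward_primer
THIO718Fseq:
  bases: ATA GAG ATC GGA AGG AAC A
  role: forward_primer
THIO1492R:
  bases: GGC TAC CTT GTT ACG ACT T
  role: reverse_primer
G123T:
  bases: CCT TCC GAT CTC TAT GCA
  role: probe
G123T-C:
  bases: CCT TCC GAT CTC TAC GCA
  role: competitor
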