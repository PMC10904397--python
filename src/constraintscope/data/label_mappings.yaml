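# Nomenclature-cleaning tables for multi-study germline variant reports.
# Keys are matched case-insensitively after trimming and collapsing
# whitespace; values are the harmonized vocabulary.  The ontology map covers
# common Sequence Ontology terms and the free-text synonyms seen in published
# supplementary tables; users can extend either map at run time.
ontology:
  # frameshift
  frameshift: frameshift
  frameshift_variant: frameshift
  frame shift: frameshift
  frame_shift: frameshift
  fs: frameshift
  frameshift insertion: frameshift
  frameshift deletion: frameshift
  frameshift indel: frameshift
  # nonsense
  nonsense: nonsense
  stop_gained: nonsense
  stopgain: nonsense
  stop gained: nonsense
  stop gain: nonsense
  premature stop: nonsense
  nonsense_variant: nonsense
  # splice
  splice_donor: splice_donor
  splice_donor_variant: splice_donor
  splice donor: splice_donor
  splice_acceptor: splice_acceptor
  splice_acceptor_variant: splice_acceptor
  splice acceptor: splice_acceptor
  splice_region: splice_region
  splice_region_variant: splice_region
  splice region: splice_region
  # missense
  missense: missense
  missense_variant: missense
  missense mutation: missense
  nonsynonymous snv: missense
  non-synonymous: missense
  # in-frame indels
  inframe_indel: inframe_indel
  inframe_deletion: inframe_indel
  inframe_insertion: inframe_indel
  in-frame deletion: inframe_indel
  in-frame insertion: inframe_indel
  nonframeshift deletion: inframe_indel
  nonframeshift insertion: inframe_indel
  # synonymous
  synonymous: synonymous
  synonymous_variant: synonymous
  silent: synonymous
  other: other
pathogenicity:
  other: other
  p: P
  pathogenic: P
  'c5: pathogenic': P
  known pathogenic: P
  path: P
  lp: LP
  pp: LP
  likely pathogenic: LP
  'c4: likely pathogenic': LP
  likely_pathogenic: LP
  probably pathogenic: LP
  vus: VUS
  'c3: uncertain significance': VUS
  uncertain significance: VUS
  variant of uncertain significance: VUS
  uncertain: VUS
zygosity:
  het: monoallelic
  heterozygous: monoallelic
  monoallelic: monoallelic
  hom: biallelic
  homozygous: biallelic
  biallelic: biallelic
  compound heterozygous: biallelic
  comp het: biallelic
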