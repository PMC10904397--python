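# Reader dialects for per-gene constraint metrics tables.
# Each entry maps canonical in-memory column names to the source file's
# column names.  "synthetic" is this package's own schema (identity map);
# "gnomad" matches the public gnomAD v2.1.1 "lof_metrics by gene" file.
synthetic:
  gene_symbol: gene_symbol
  transcript_id: transcript_id
  canonical: canonical
  cds_length: cds_length
  obs_lof: obs_lof
  exp_lof: exp_lof
  loe: loe
  loelf: loelf
  loeuf: loeuf
  obs_mis: obs_mis
  exp_mis: exp_mis
  moe: moe
  moelf: moelf
  moeuf: moeuf
gnomad:
  gene_symbol: gene
  transcript_id: transcript
  canonical: canonical
  cds_length: cds_length
  obs_lof: obs_lof
  exp_lof: exp_lof
  loe: oe_lof
  loelf: oe_lof_lower
  loeuf: oe_lof_upper
  obs_mis: obs_mis
  exp_mis: exp_mis
  moe: oe_mis
  moelf: oe_mis_lower
  moeuf: oe_mis_upper
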