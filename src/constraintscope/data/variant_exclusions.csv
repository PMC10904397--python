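gene_symbol,hgvs_c,reason
APC,c.3920T>A,low-risk allele (p.Ile1307Lys); cancer risk factor rather than a CPS-causing variant
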