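gene_a	gene_b
VEGFA	BCL2
RRM1	BCL2
ERBB2	BCL2
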