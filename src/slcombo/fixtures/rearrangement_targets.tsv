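drug_id	gene
docetaxel	TUBB
zoledronic_acid	FDPS
iniparib	PARP1
gemcitabine	RRM1
gemcitabine	TYMS
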