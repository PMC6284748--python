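combo_id	indication	source	drugs
388	Breast Neoplasms	trial	iniparib;gemcitabine
390	Breast Neoplasms	trial	docetaxel;zoledronic_acid
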