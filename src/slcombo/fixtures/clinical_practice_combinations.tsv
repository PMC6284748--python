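combo_id	indication	source	drugs
P001	Breast Neoplasms	practice	bevacizumab;docetaxel
P002	Breast Neoplasms	practice	bevacizumab;paclitaxel
P003	Breast Neoplasms	practice	gemcitabine;docetaxel
P004	Breast Neoplasms	practice	gemcitabine;paclitaxel
P005	Breast Neoplasms	practice	trastuzumab;docetaxel
P006	Breast Neoplasms	practice	trastuzumab;paclitaxel
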