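rsid	position	effect_allele	other_allele	beta	se	pvalue
rs10822184	65007159	T	C	0.000928	0.001160	0.423711
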