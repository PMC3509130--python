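run_id	sample_id	group	n_spectra
r1	s1	H	80
r2	s1	H	100
r3	s2	ICD	120
r4	s2	ICD	100
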