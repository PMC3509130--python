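spectrum_id	run_id	sample_id	peptide	prev_aa	next_aa	charge	xcorr	deltcn	ppm_error	protein_ids	is_decoy
sp01	r1	s1	MAGWTEK	-	L	2	2.50	0.10	2.0	A1;A2;X1	False
sp02	r1	s1	LVNDESTAR	K	F	2	2.49	0.10	0.0	A1;A2	False
sp03	r1	s1	FGQYLMK	R	E	2	3.00	0.15	10.0	A1	False
sp04	r2	s1	FGQYLIK	R	E	2	3.10	0.20	-10.1	A2	False
sp05	r2	s1	GGVTLSDNR	K	A	1	1.80	0.05	-3.0	B1	False
sp06	r2	s1	AEQILPMYK	R	T	3	3.50	0.30	1.0	B1;B2	False
sp07	r3	s2	TTSGWVADFR	K	-	2	2.80	0.10	2.0	B1	False
sp08	r3	s2	MSSTELFK	-	A	2	2.60	0.10	5.0	HUMAN01	False
sp09	r3	s2	AQWDNPLR	K	G	2	2.70	0.10	4.0	HUMAN01	False
sp10	r4	s2	ESATVWDNK	K	-	2	2.90	0.10	0.5	A1	False
sp11	r4	s2	VYEQIKDDSTAVLR	G	-	2	3.00	0.10	0.0	HUMAN01	False
sp12	r4	s2	KNDWVTASE	R	-	2	2.90	0.10	1.0	rev_A1	True
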