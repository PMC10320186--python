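# Curated per-residue physicochemical scales used for substitution deltas.
# hydrophobicity: Kyte-Doolittle hydropathy; volume: residue volume (A^3);
# polarity: Grantham polarity; flexibility: average flexibility index;
# isoelectric_point: pI of the free amino acid.
property	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
hydrophobicity	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
volume	88.6	173.4	114.1	111.1	108.5	143.8	138.4	60.1	153.2	166.7	166.7	168.6	162.9	189.9	112.7	89.0	116.1	227.8	193.6	140.0
polarity	8.1	10.5	11.6	13.0	5.5	10.5	12.3	9.0	10.4	5.2	4.9	11.3	5.7	5.2	8.0	9.2	8.6	5.4	6.2	5.9
flexibility	0.357	0.529	0.463	0.511	0.346	0.493	0.497	0.544	0.323	0.462	0.365	0.466	0.295	0.314	0.509	0.507	0.444	0.305	0.420	0.386
isoelectric_point	6.00	10.76	5.41	2.77	5.05	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.30	5.68	5.66	5.89	5.66	5.96
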