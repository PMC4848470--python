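specimen_id	species	latitude	longitude	is_reference	mapped_noncoding_pct	mapped_coding_pct	het_pct	het_coding_pct	coverage
NVG-3306	cecrops	31.524582	-93.098485	1	100.0	99.9	1.16	0.56	78.0
NVG-3307	cecrops	31.524582	-93.098485	0	88.7	97.6	1.46	0.64	14.1
NVG-3515	cecrops	30.50644	-95.08783	0	88.2	97.7	1.44	0.65	12.6
NVG-3348	isobeon	26.05681	-97.84284	0	84.4	97.8	1.79	0.82	16.5
NVG-3431	isobeon	26.22615	-98.43653	0	84.2	97.7	1.83	0.84	14.5
NVG-3978	isobeon	32.85531	-96.71484	0	83.1	97.4	1.58	0.71	14.1
NVG-4166	isobeon	29.72914	-93.87508	0	83.2	97.4	1.59	0.71	13.0
NVG-3033	isobeon	9.8833	-84.0333	0	82.5	96.0	1.96	1.04	13.0
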