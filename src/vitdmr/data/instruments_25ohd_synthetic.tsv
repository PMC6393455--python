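rsid	effect_allele	other_allele	eaf	beta	se	pvalue	n
rs3755967	T	C	0.284	-0.0852	0.0031	1e-300	79366
rs12785878	G	T	0.748	0.0341	0.0029	8.1e-32	79366
rs10741657	A	G	0.398	0.0298	0.0028	2.4e-26	79366
rs17216707	T	C	0.785	0.0253	0.0033	9.7e-15	79366
rs117913124	A	G	0.026	-0.1962	0.0158	3.3e-36	42274
rs8018720	G	T	0.181	-0.0173	0.0031	4.7e-09	79366
rs10745742	T	C	0.604	0.0162	0.0027	1.9e-09	79366
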