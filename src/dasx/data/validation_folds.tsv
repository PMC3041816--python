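gene	probeset_id	si_d7	fold_d7	direction
Abi2	4987109	1.67	7.44	d7/d0
Aff3	5291502	3.81	53.87	d7/d0
Ank3	5060679	-3.30	4.78	d0/d7
Aplp2	5477899	2.04	5.88	d7/d0
Arhgef12	5209805	-1.44	1.90	d0/d7
Atf2	5194737	1.85	5.45	d7/d0
Atp1a3	5385869	-2.71	16.88	d0/d7
Bai2	5286600	-2.05	5.20	d7/d0
Bcl11a	4969426	-1.43	2.82	d7/d0
Clta	4399984	3.05	5.93	d7/d0
Dlg3	5344442	5.39	52.04	d7/d0
Epb4.1l3	5517310	2.76	5.78	d7/d0
Epb4.1l3	4866829	2.04	2.54	d7/d0
Fam113a	4648309	-2.98	3.74	d7/d0
Fchsd2	4408143	3.36	19.52	d7/d0
Gnao1	4489479	-1.62	2.12	d0/d7
Kif1b	4352234	2.15	5.70	d7/d0
Kif21b	5130589	2.85	111.60	d7/d0
Kif2a	5345537	4.23	135.44	d7/d0
Neo1	5491604	1.77	6.84	d7/d0
Neo1	4604088	5.90	31.00	d7/d0
Plekha5	5343636	1.59	17.93	d7/d0
Rbm9	5479607	2.04	7.41	d0/d7
Rnf138	4323558	2.31	1.17	d7/d0
Rufy3	4321833	-1.85	2.01	d0/d7
Snap91	4960676	2.78	14.98	d0/d7
Tmem219	5381697	-1.91	1.58	d0/d7
Tpd52l2	4473030	1.86	12.47	d7/d0
Tprkb	5267179	-2.75	1.00	d7/d0
Zfp326	5023736	2.31	2.94	d0/d7
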