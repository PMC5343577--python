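species	accession	pcg_t	pcg_c	pcg_a	pcg_g	pcg_length	pcg_at	pcg_at_skew	pcg_gc_skew	rrnl_length	rrnl_at	rrns_length	rrns_at
Episyrphus balteatus	KU351241	39.90	11.66	38.95	9.49	11220	78.85	-0.0121	-0.1024	1338	84.60	804	83.96
Eupeodes corollae	KU379658	39.25	11.66	39.59	9.51	11211	78.83	0.0043	-0.1016	1334	84.78	795	83.14
Ocyptamus sativus	KT272862	39.71	11.68	39.26	9.35	11175	78.97	-0.0058	-0.1106	1314	84.40	778	82.78
Simosyrphus grandicornis	DQ866050	39.75	11.81	39.09	9.35	11208	78.84	-0.0084	-0.1164	1339	84.99	804	83.83
Megaselia scalaris	KF974742	37.26	14.81	37.66	10.26	11301	74.92	0.0053	-0.1814	1318	81.03	786	79.64
Bactrocera dorsalis	DQ845759	32.94	17.85	38.16	11.05	11175	71.10	0.0734	-0.2353	1333	79.52	790	74.94
Drosophila melanogaster	JQ686693	38.16	12.78	39.06	10.00	11169	77.22	0.0117	-0.1219	1323	82.84	786	80.15
Fergusonina taylori	HQ872008	36.13	14.19	39.92	9.76	11160	76.05	0.0498	-0.1852	1306	82.54	780	82.05
Nemopoda mamaevi	KM605250	35.84	16.28	36.88	11.00	11181	72.72	0.0144	-0.1934	1321	80.62	783	77.65
Haematobia irritans	DQ029097	39.04	12.29	38.63	10.04	11178	77.67	-0.0053	-0.1010	1321	82.66	784	78.83
Musca domestica	KT444442	37.84	13.61	38.24	10.31	11184	76.08	0.0053	-0.1379	1326	81.00	783	78.29
Chrysomya putoria	AF352790	36.74	14.59	38.23	10.44	11187	74.97	0.0199	-0.1657	1329	81.79	785	76.94
Dermatobia hominis	AY463155	35.96	15.08	39.31	9.65	11187	75.27	0.0445	-0.2198	1324	83.08	788	78.68
Pollenia rudis	JX913761	37.29	14.14	38.52	10.04	11172	75.81	0.0163	-0.1695	1328	81.63	448	74.11
Ravinia pernix	KM676414	36.88	14.33	38.63	10.17	11181	75.50	0.0232	-0.1698	1328	82.08	786	77.48
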