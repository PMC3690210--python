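name	block	d	Ka	Ks	KaKs
Orthologous group 1	orthologous	0.0234	0.0058	0.0819	0.0711
Orthologous group 2	orthologous	0.0374	0.0188	0.1002	0.1874
Orthologous group 3	orthologous	0.0149	0.0000	0.0642	0.0000
Orthologous group 4	orthologous	0.0163	0.0010	0.0674	0.0153
Orthologous group 5	orthologous	0.0204	0.0000	0.0902	0.0000
Orthologous group 6	orthologous	0.0362	0.0156	0.1050	0.1488
Orthologous group 7	orthologous	0.0510	0.0262	0.1268	0.2064
Orthologous group 8	orthologous	0.0366	0.0184	0.0899	0.2047
Orthologous group 9	orthologous	0.0107	0.0005	0.0483	0.0107
Orthologous group 10	orthologous	0.0777	0.0606	0.1349	0.4487
Orthologous group 11	orthologous	0.0094	0.0000	0.0416	0.0000
Orthologous group 12	orthologous	0.0186	0.0006	0.0831	0.0069
Orthologous group 13	orthologous	0.0207	0.0007	0.0893	0.0077
Orthologous group 14	orthologous	0.0125	0.0005	0.0563	0.0089
Complex group 1	complex	0.0208	0.0136	0.0445	0.3067
Complex group 2	complex	0.0183	0.0011	0.0755	0.0146
Complex group 3	complex	0.0350	0.0364	0.0305	1.1935
Complex group 4	complex	0.2291	0.2027	0.3317	0.6112
Complex group 5	complex	0.1455	0.1362	0.1770	0.7697
Complex group 6	complex	0.0494	0.0183	0.1570	0.1164
Complex group 7	complex	0.0364	0.0236	0.0793	0.2973
Complex group 8	complex	0.0760	0.0674	0.1053	0.6399
Complex group 9	complex	0.0324	0.0199	0.0754	0.2647
Complex group 10	complex	0.0945	0.0735	0.1574	0.4668
Complex group 11	complex	0.0555	0.0312	0.1382	0.2255
Complex group 12	complex	0.0392	0.0123	0.1343	0.0919
Complex group 13	complex	0.0217	0.0081	0.0657	0.1229
Complex group 14	complex	0.0516	0.0376	0.0928	0.4054
Complex group 15	complex	0.0330	0.0022	0.1388	0.0155
Complex group 16	complex	0.0380	0.0158	0.1133	0.1397
Complex group 17	complex	0.0265	0.0068	0.0924	0.0736
Complex group 18	complex	0.0630	0.0540	0.0931	0.5797
Complex group 19	complex	0.0107	0.0000	0.0466	0.0000
Complex group 20	complex	0.0554	0.0482	0.0816	0.5909
Homo sapiens (human)	species	0.8350	0.6650	1.3310	0.4996
Callithrix jacchus (marmoset)	species	0.7360	0.5890	1.2230	0.4816
Gorilla gorilla (gorilla)	species	0.8510	0.6890	1.3410	0.5138
Macaca mulatta (rhesus monkey)	species	0.9040	0.7270	1.4500	0.5014
Nomascus leucogenys (gibbon)	species	1.0050	0.8630	1.5680	0.5504
Pan troglodytes (chimpanzee)	species	0.9980	0.8300	1.4780	0.5616
Pongo pygmaeus abelii (orangutan)	species	0.8830	0.7050	1.5140	0.4657
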