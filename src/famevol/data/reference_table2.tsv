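group	Hsa	Ptr	Ggo	Ppy	Nle	Mmu	Cja	total
Complex group 1	3	4	2	1	0	0	0	10
Complex group 2	2	1	1	1	1	2	0	8
Complex group 3	0	0	0	0	0	0	4	4
Complex group 4	0	1	1	1	0	0	0	3
Complex group 5	0	1	1	0	0	1	0	3
Complex group 6	1	0	1	1	1	2	0	6
Complex group 7	0	0	0	0	0	0	6	6
Complex group 8	0	1	1	1	1	1	0	5
Complex group 9	1	1	1	0	1	1	1	6
Complex group 10	1	1	1	2	0	0	1	6
Complex group 11	1	1	1	1	0	1	1	6
Complex group 12	1	1	1	1	1	1	2	8
Complex group 13	1	1	2	1	1	1	0	7
Complex group 14	0	0	1	1	0	1	1	4
Complex group 15	1	1	0	1	1	1	1	6
Complex group 16	1	1	2	1	1	1	1	8
Complex group 17	1	1	0	1	1	1	1	6
Complex group 18	1	1	1	2	1	3	1	10
Complex group 19	1	1	0	1	0	1	1	5
Complex group 20	0	2	0	0	1	1	0	4
Total	16	20	17	17	11	19	21	121
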