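cluster_id	gene_count	mapped_genes
1	11	11
2	24	23
3	15	15
4	15	15
5	8	8
6	8	8
7	7	7
8	19	18
9	13	13
10	12	12
11	4	4
12	15	14
13	10	10
14	6	6
15	23	21
16	18	17
17	3	3
18	22	22
19	36	36
20	22	21
21	15	15
22	51	41
23	5	5
24	39	39
25	6	6
26	16	16
27	61	53
28	21	18
29	34	32
30	37	35
31	40	31
32	27	27
33	14	14
34	10	10
35	17	16
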