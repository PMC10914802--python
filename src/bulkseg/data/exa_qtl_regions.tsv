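qtl	chrom	start_bp	end_bp	n_genes	n_snps
1	chr01	34124274	35482929	33	31129
2	chr01	60085436	60330764	14	6246
3	chr01	85175189	85216376	12	999
4	chr02	39999989	40404248	45	10045
5	chr02	45414396	45796712	47	3040
6	chr05	88	8263777	753	192743
7	chr06	45262468	48153426	232	61076
8	chr06	51855603	55730666	414	61111
9	chr06	58242043	59532090	150	24262
10	chr07	56689152	56752834	1	873
11	chr08	56234261	56933939	70	12778
12	chr09	11242995	14240453	99	76843
13	chr12	19226	1446194	150	30868
14	chr12	2120460	4718278	244	63849
15	chr12	58579071	59261529	61	13601
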