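cell_a	cell_b	dhs_a	dhs_b	shared	over_a	over_a_shared	over_b	over_b_shared
CD4	CD8	84830	60890	49365	14772	10600	3874	3584
CD4	CD14	84830	109647	47887	14819	6219	17932	7663
CD4	CD19	84830	89660	43282	18525	10423	19439	13018
CD4	CD56	84830	69966	54739	17745	14611	2616	2526
CD4	SpinalCord	84830	197751	34812	24652	9158	93152	10233
CD4	Fibroblasts	84830	193546	40240	21473	7087	118265	11741
CD8	CD14	60890	109647	32185	11602	6529	55650	12546
CD8	CD19	60890	89660	32350	8780	5520	28708	15549
CD8	CD56	60890	69966	51965	1458	1428	335	330
CD8	SpinalCord	60890	197751	27631	13128	5444	110950	11330
CD8	Fibroblasts	60890	193546	30237	13734	5894	156418	15573
CD14	CD19	109647	89660	36349	48031	15909	27111	18140
CD14	CD56	109647	69966	33900	54850	17845	7842	5357
CD14	SpinalCord	109647	197751	33141	53731	13584	96856	13563
CD14	Fibroblasts	109647	193546	45179	37641	8383	108482	12677
CD19	CD56	89660	69966	35766	31561	19315	5553	4130
CD19	SpinalCord	89660	197751	31858	28993	13118	97388	14826
CD19	Fibroblasts	89660	193546	30831	32531	13760	138301	20224
CD56	SpinalCord	69966	197751	28731	8633	4404	110996	13892
CD56	Fibroblasts	69966	193546	31469	9237	4769	154923	20024
SpinalCord	Fibroblasts	197751	193546	64733	24756	5497	35202	9461
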