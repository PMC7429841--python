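chrom	level	n_events	end_bp	start_bp	span_bp	span_mb	printed_rate_n_per_mb
A01	chrom	743	105923929	287710	105636219	105.64	7.03
A02	chrom	666	92619538	32207	92587331	92.59	7.19
A03	chrom	1154	133100052	57469	133042583	133.04	8.67
A04	chrom	731	119909962	36037	119873925	119.87	6.10
A05	chrom	932	108244824	9936	108234888	108.23	8.61
A06	chrom	824	110568156	84772	110483384	110.48	7.46
A07	chrom	575	77818488	106281	77712207	77.71	7.40
A08	chrom	767	48912733	87493	48825240	48.83	15.71
A09	chrom	782	118990609	13322	118977287	118.98	6.57
A10	chrom	702	107163086	11205	107151881	107.15	6.55
B01	chrom	1102	136834735	135664	136699071	136.70	8.06
B02	chrom	977	108513667	169195	108344472	108.34	9.02
B03	chrom	1718	135528322	75576	135452746	135.45	12.68
B04	chrom	1094	133156247	52357	133103890	133.10	8.22
B05	chrom	1313	149413871	104928	149308943	149.31	8.79
B06	chrom	1248	136646814	75883	136570931	136.57	9.14
B07	chrom	1082	125895165	69248	125825917	125.83	8.60
B08	chrom	957	129061483	99756	128961727	128.96	7.42
B09	chrom	1225	146488426	24230	146464196	146.46	8.36
B10	chrom	1218	135754341	79242	135675099	135.68	8.98
A_subgenome	subgenome	7876	1023251377	726432	1022524945	1022.52	7.70
B_subgenome	subgenome	11934	1337293071	886079	1336406992	1336.41	8.93
Total	genome	19810	2360544448	1612511	2358931937	2358.93	8.40
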