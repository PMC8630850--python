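chrom	n_nondmr	n_dmr	accuracy	f1	precision	recall
1	13959	5307	0.9643	0.9450	0.9304	0.9601
2	14090	3990	0.9815	0.9572	0.9692	0.9456
3	7742	2664	0.9705	0.9467	0.9291	0.9653
4	7199	2900	0.9710	0.9500	0.9314	0.9695
5	7538	2805	0.9639	0.9339	0.9078	0.9616
6	6556	2151	0.9710	0.9459	0.9300	0.9623
7	6636	2349	0.9458	0.8810	0.9096	0.8818
8	4676	1955	0.9617	0.9366	0.9220	0.9517
9	5136	1867	0.9378	0.8906	0.8460	0.9403
10	2728	1804	0.9323	0.9220	0.8756	0.9737
11	3145	1365	0.9498	0.9229	0.9018	0.9451
12	2502	1284	0.9540	0.9405	0.9030	0.9812
13	5471	1789	0.9516	0.9032	0.9042	0.9022
14	5895	1844	0.9647	0.9296	0.9333	0.9260
15	4934	1802	0.9513	0.9157	0.8986	0.9337
16	4286	1500	0.9559	0.9176	0.9073	0.9281
17	3606	1533	0.9274	0.8846	0.8079	0.9777
18	3591	1425	0.9421	0.8995	0.8651	0.9368
19	2108	1195	0.9416	0.9208	0.9042	0.9382
20	1550	1023	0.9440	0.9247	0.8739	0.9810
X	13664	1699	0.9654	0.8206	0.9096	0.7476
Y	151	79	0.8842	0.8423	0.7246	1.0
All	126163	44330	0.9753	0.9502	0.9556	0.9488
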