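target	length	PRSDA_gdtts	PRSDA_crmsd	MODELLER_gdtts	MODELLER_crmsd	ITASSER_gdtts	ITASSER_crmsd
1AOY	62	0.9597	0.765	0.9919	0.585	0.9274	1.195
1BQ9	52	0.9952	0.501	0.9952	0.469	0.9904	0.613
1CEW	108	0.7361	2.606	0.8704	2.74	0.7986	2.447
1CSP	65	0.9697	0.633	0.9962	0.475	0.9053	1.19
1DI2	69	0.9638	0.802	0.9746	0.676	0.9783	0.614
1DTJ	73	0.9692	0.924	0.9658	1.533	0.9623	0.818
1GNU	115	0.9717	0.844	0.9804	0.799	0.8913	1.261
1GYV	119	0.9979	0.330	0.9958	0.456	0.9328	0.621
1ITP	68	0.9154	1.128	0.9228	1.079	0.9384	0.987
1JNU	97	0.9871	0.637	0.9897	0.583	0.9201	1.203
1KJS	55	0.7045	2.724	0.7545	2.83	0.7455	3.198
1O2F	68	0.9816	0.703	0.9853	0.66	0.9338	0.873
1OGW	74	0.9595	1.824	0.9392	1.923	0.9054	1.837
1PGX	56	0.9955	0.520	0.9955	0.501	0.942	0.938
1R69	69	0.9637	0.767	0.9597	0.97	0.9274	1.111
1SHF	59	0.9958	0.503	0.9958	0.491	0.9534	1.186
1TEN	89	0.9775	0.745	0.5337	3.761	0.5309	3.677
1VCC	77	0.9903	0.589	0.9968	0.527	0.9513	1.045
256B	106	0.9858	0.568	0.9976	0.46	0.9316	1.26
2CR7	60	0.7421	2.129	0.877	1.465	0.9127	1.275
2PCY	99	0.9823	0.656	0.9924	0.485	0.852	0.905
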