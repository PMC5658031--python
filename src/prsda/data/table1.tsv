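target	length	PRSDA_gdt2	PRSDA_crmsd	MODELLER_gdt2	MODELLER_crmsd
3D3N	247	0.8947	2.37	0.906	2.68
3DBI	269	0.7361	2.778	0.704	2.71
3D4O	278	0.5683	2.897	0.555	2.77
3DO6	509	0.9136	1.676	0.919	1.31
3CKW	231	0.9091	1.567	0.863	1.48
3DTO	180	0.4889	5.571	0.810	3.03
3D7Q	101	0.9208	1.523	0.929	1.35
3DJB	174	0.7931	3.12	0.819	2.18
3D3U	360	0.8667	2.048	0.918	1.72
3DA1	462	0.7684	4.037	0.849	2.01
3DFH	352	0.8920	1.567	0.962	1.3
3CTV	90	0.6111	9.217	0.772	3.04
3DO5	277	0.6679	5.124	0.653	2.82
3DMB	142	0.5704	5.011	0.628	3.07
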