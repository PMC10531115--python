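rsid	chrom	pos_bp	cm	IBS	YRI	NA
rs7528419	1	109817192	138.712247	0.064	0.09053	0.84549
rs17465982	1	222837939	246.478996	0.0074	0.67445	0.3182
rs9349379	6	12903957	28.8898785	0.0172	0.41137	0.57144
rs10455872	6	161010118	177.557204	0.5659	0.41854	0.01556
rs4722172	7	22786532	40.0928349	0.0329	0.39048	0.57665
rs11066301	12	112871372	130.305862	0.1981	0.00386	0.79809
rs11057830	12	125307053	149.857655	0.1827	0.16692	0.65043
rs10851907	15	78915864	102.193041	0.0029	0.45321	0.54385
rs55791371	19	11188153	31.8736735	0.0027	0.08713	0.91016
rs28451064	21	35593827	36.2865085	0.0789	0.51911	0.40204
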