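rsid	chrom	pos_bp	relation
rs7412	19	45412079	ACS
rs76863441	6	46677098	ACS
rs12740374	1	109817590	ACS
rs35610040	20	23616469	ACS
rs62471956	7	99421085	ACS
rs10455872	6	161010118	ACS
rs2733201	15	44408401	ACS
rs11638352	15	44293137	ACS
rs186696265	6	161111700	ACS
rs188845491	7	99286639	ACS
rs147642358	7	98932759	ACS
rs140607780	7	100103523	ACS
rs9295128	6	160751531	ACS
rs140104968	7	99543627	ACS
rs117714106	14	84804488	ACS
rs117038461	7	99841354	ACS
rs144972973	15	44564692	ACS
rs201052613	1	172995643	ACS
rs11057830	12	125307053	ACS
rs189889864	9	107396924	ACS
rs140570886	6	161013013	CAD
rs9349379	6	12903957	CAD
rs602633	1	109821511	CAD
rs6511720	19	11202306	CAD
rs55791371	19	11188153	CAD
rs7173743	15	79141784	CAD
rs28451064	21	35593827	CAD
rs6728861	2	203873743	CAD
rs72934535	2	203968973	CAD
rs115654617	2	203893999	CAD
rs147555597	6	160911596	CAD
rs2327429	6	134209837	CAD
rs7770628	6	161018174	CAD
rs3184504	12	111884608	CAD
rs974819	11	103660567	CAD
rs1966248	6	134159622	CAD
rs35158675	1	222829550	CAD
rs17114046	1	56966350	CAD
rs17465982	1	222837939	CAD
rs7137828	12	111932800	CAD
rs118039278	6	160985526	PAD
rs1537372	9	22103183	PAD
rs10851907	15	78915864	PAD
rs6025	1	169519049	PAD
rs2107595	7	19049388	PAD
rs7528419	1	109817192	PAD
rs11066301	12	112871372	PAD
rs4722172	7	22786532	PAD
rs7903146	10	114758349	PAD
rs505922	9	136149229	PAD
rs4746743	10	69996292	CLOPIDOGREL
rs1900005	10	69998055	CLOPIDOGREL
rs12098677	10	69999026	CLOPIDOGREL
rs9980291	21	39485558	CLOPIDOGREL
rs1900003	10	70004551	CLOPIDOGREL
rs1900002	10	70004552	CLOPIDOGREL
rs4745950	10	69996455	CLOPIDOGREL
rs3796692	4	185205210	CLOPIDOGREL
rs4021557	17	21225519	CLOPIDOGREL
rs7916697	10	69991853	CLOPIDOGREL
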