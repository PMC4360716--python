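dataset	sequence_id	length	clade	markers	phoH	crispr_host	tetra_host
HiSeq Viromes	Pavin_2013_4m_8	105162	Far_T4_1	g23; g20; g17	+	Clostridia ?	Anaplasmataceae ?
HiSeq Viromes	Pavin_2013_4m_10	97022	Far_T4_3	g23; g20; g17	+		
HiSeq Viromes	Pavin_2013_4m_12	86378	Far_T4_1	g23; g20; g17	+		
HiSeq Viromes	Pavin_2013_8m_12	59230	Far_T4_1	g23; g20; g17	+		
HiSeq Viromes	Pavin_2013_4m_33	55178	Far_T4_1	g23; g20; g17	+		
HiSeq Viromes	Pavin_2013_4m_40	51859	Far_T4_1	g23; g20; g17	+		Anaplasmataceae ?
HiSeq Viromes	Pavin_2013_8m_18	51839	Far_T4_1	g23; g20; g17	+		Anaplasmataceae ?
HiSeq Viromes	Pavin_2013_4m_55	43868	Far_T4_1	g23; g20; g17 (partial)	+		
HiSeq Viromes	Pavin_2013_4m_62	40954	Far_T4_5	g23			
HiSeq Viromes	Pavin_2013_4m_77	36429	Far_T4_4	g23	+		
HiSeq Viromes	Pavin_2013_8m_34	35829	Far_T4_4	g23	+		
HiSeq Viromes	Pavin_2013_8m_73	27012	Far_T4_4	g23	+		
HiSeq Viromes	Pavin_2013_4m_174	23723	Far_T4_4	g23	+		
HiSeq Viromes	Pavin_2013_4m_229	20766	Far_T4_1	g23	+		
HiSeq Viromes	Pavin_2013_4m_232	20663	Far_T4_4	g23; g20; g17			
HiSeq Viromes	Pavin_2013_8m_128	19577	Far_T4_1	g23	+		
HiSeq Viromes	Pavin_2013_8m_153	17698	Far_T4_4	g23	+		
HiSeq Viromes	Pavin_2013_4m_295	17576	Far_T4_3	g23			
HiSeq Viromes	Pavin_2013_8m_177	16514	Far_T4_4	g23	+		
HiSeq Viromes	Pavin_2013_4m_335	16154	Far_T4_1	g23; g20; g17	+	Bacilli ?	
HiSeq Viromes	Pavin_2013_4m_405	14371	Far_T4_1	g23	+		
HiSeq Viromes	Pavin_2013_8m_232	14013	Far_T4_1	g23; g20; g17 (partial)	+		
HiSeq Viromes	Pavin_2013_4m_436	13727	Far_T4_1	g23	+		
HiSeq Viromes	Pavin_2013_4m_473	13214	Far_T4_5	g23			
HiSeq Viromes	Pavin_2013_8m_261	13214	Far_T4_5	g23			
HiSeq Viromes	Pavin_2013_4m_512	12683	Far_T4_1	g23	+		
HiSeq Viromes	Pavin_2013_4m_546	12156	Far_T4_1	g23	+		
HiSeq Viromes	Pavin_2013_8m_320	11847	Far_T4_5	g23			
HiSeq Viromes	Pavin_2013_8m_328	11687	Far_T4_1	g23; g20; g17		Bacilli ?	
HiSeq Viromes	Pavin_2013_4m_634	10875	Far_T4_4	g23			
HiSeq Viromes	Pavin_2013_4m_647	10681	Far_T4_4	g23; g20			
HiSeq Viromes	Pavin_2013_4m_691	10076	Far_T4_1	g23; g20			
454 Viromes	Pavin_2009_08187	5217	Far_T4_1	g23			
454 Viromes	Bourget_2009_19709	2282	Far_T4_1	g23	+		
454 Viromes	Bourget_2009_14420	3756	Far_T4_1	g23	+		
454 Viromes	Bourget_2009_12531	2307	Far_T4_1	g23	+		
454 Viromes	Bourget_2009_12442	2049	Far_T4_1	g23	+		
454 Viromes	Pavin_2009_09564	1527	Far_T4_4	g23			
454 Viromes	Bourget_2009_57	1630	Far_T4_4	g23			
454 Viromes	Bourget_2009_02710	2702	Far_T4_1	g23			
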