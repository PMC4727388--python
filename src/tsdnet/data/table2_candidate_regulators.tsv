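comparison	gene_id	gene_symbol	description	molecule_type	expression	timespan
MPT Day 0 vs MPT Day 3	XLOC_015643	CEBPA	CCAAT/enhancer binding protein (C/EBP), alpha	Transcription factor	Up	Short
MPT Day 0 vs MPT Day 3	XLOC_013275	KDM6B	Lysine (K)-specific demethylase 6B	Transcription regulator	Down	Long
MPT Day 0 vs MPT Day 3	XLOC_012144	LOC102562106	Protein Jumonji-like	Transcription regulator	Down	Long
MPT Day 0 vs MPT Day 3	XLOC_012145	LOC102561337	Protein Jumonji-like	Transcription regulator	Down	Long
MPT Day 0 vs MPT Day 3	XLOC_017186	CRABP2	Cellular retinoic acid binding protein 2	Transporter	Down	Short
MPT Day 0 vs MPT Day 3	XLOC_017840	MYBL2	v-myb avian myeloblastosis viral oncogene homolog-like 2	Transcription factor	Down	Short
MPT Day 0 vs MPT Day 3	XLOC_006860	LOC102569158	Protein Wnt-11-like, transcript variant X2	Other	Down	Short
MPT Day 3 vs MPT Day 6	XLOC_006860	LOC102569158	Protein Wnt-11-like, transcript variant X2	Other	Up	Short
MPT Day 3 vs MPT Day 6	XLOC_020119	TNNI2	Troponin I type 2 (skeletal, fast)	Enzyme	Up	Short
MPT Day 3 vs MPT Day 6	XLOC_009637	MYCL	v-myc avian myelocytomatosis viral oncogene lung carcinoma derived homolog	Transcription factor	Up	Short
MPT Day 3 vs MPT Day 6	XLOC_006593	LOC102560544	Elongation factor 1-alpha-like	Other	Up	Short
MPT Day 3 vs MPT Day 6	XLOC_003318	LOC102577358	Duplex and mab-3 related transcription factor 3-like	Transcription factor	Up	Long
MPT Day 3 vs MPT Day 6	XLOC_013828	LOC102573123	Transcription factor SOX-9-like	Transcription factor	Up	Long
MPT Day 3 vs MPT Day 6	XLOC_014546	LOC102576325	Serine/threonine-protein kinase PAK 1-like	Protein kinase	Up	Long
MPT Day 3 vs MPT Day 6	XLOC_015643	CEBPA	CCAAT/enhancer binding protein (C/EBP), alpha	Transcription factor	Up	Short
MPT Day 3 vs MPT Day 6	XLOC_012336	SPTB	Spectrin, beta, erythrocytic, cpytranscript variant X1	Other	Up	Short
MPT Day 3 vs MPT Day 6	XLOC_018228	LOC102559361	Endothelin B receptor-like	Receptor	Down	Ambiguous
MPT Day 3 vs MPT Day 6	XLOC_003353	EMX1	Empty spiracles homeobox 1	Transcription factor	Down	Short
MPT Day 6 vs MPT Day 12	XLOC_013828	LOC102573123	Transcription factor SOX-9-like	Transcription factor	Up	Long
MPT Day 6 vs MPT Day 12	XLOC_019721	HOXC10	Homeobox C10	Transcription factor	Down	Ambiguous
MPT Day 6 vs MPT Day 12	XLOC_001928	ARX	Aristaless related homeobox	Transcription factor	Down	Long
FPT Day 0 vs FPT Day 3	XLOC_003878	FABP4	Fatty acid binding protein 4, adipocyte	Transporter	Up	Ambiguous
FPT Day 0 vs FPT Day 3	XLOC_000567	LUM	Lumican	Other	Up	Short
FPT Day 0 vs FPT Day 3	XLOC_012101	TAGLN3	Transgelin 3	Other	Down	Short
FPT Day 0 vs FPT Day 3	XLOC_007693	FZD5	Frizzled family receptor 5	Receptor	Down	Short
FPT Day 0 vs FPT Day 3	XLOC_017000	LOC102563625	cGMP-dependent 3', 5'-cyclic phosphodiesterase-like	Enzyme	Down	Short
FPT Day 6 vs FPT Day 12	XLOC_001005	LOC102577040	Forkhead box protein L2-like	Transcription factor	Up	Long
FPT Day 6 vs FPT Day 12	XLOC_006272	EYA1	Eyes absent homolog 1 (Drosophila), transcript variant X1	Phosphatase	Up	Long
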