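description	accession	log2fc	fdr	direction	primary_ontology
Uncoupling protein 2 (mitochondrial, proton carrier)	XM_006257947.1	1.47	2.63E-03	up	P: liver regeneration
UDP-N-acetyl-alpha-D-galactosamine:polypeptide N-acetylgalactosaminyltransferase 5	XM_006262802.1	1.46	2.63E-03	up	C: Golgi membrane
Eukaryotic translation initiation factor 4A2	XM_006262029.1	1.18	2.63E-03	up	F: translation initiation factor activity
Uroplakin 3A	XM_006265339.1	1.09	2.63E-03	up	C: integral to membrane
Low-density lipoprotein receptor-related protein 1-like	XM_006265415.1	1.09	2.63E-03	up	P: lipoprotein transport
Acyl-coenzyme A synthetase ACSM4, mitochondrial-like	XM_006273705.1	1.01	2.63E-03	up	F: catalytic activity
Solute carrier family 1 (glutamate/neutral amino acid transporter), member 4	XM_006264916.1	0.97	2.63E-03	up	P: proline transmembrane transport
Transient receptor potential cation channel, subfamily C, member 4 associated protein	XM_006258376.1	0.91	2.63E-03	up	C: Cul4A-RING ubiquitin ligase complex
CCAAT/enhancer binding protein (C/EBP), alpha	XM_006274301.1	0.90	2.63E-03	up	P: regulation of cell proliferation
Methylcrotonoyl-CoA carboxylase beta chain, mitochondrial-like	XM_006273834.1	0.86	2.63E-03	up	F: ligase activity
Myosin XVIIIB	XM_006261765.1	0.86	2.63E-03	up	C: nucleolus
Chromosome unknown open reading frame, human C1orf63	XM_006276772.1	0.80	2.63E-03	up	N/A
Interferon-related developmental regulator 1, transcript variant X2	XM_006278568.1	0.69	2.63E-03	up	P: myoblast fate determination
Espin-like	XM_006276123.1	0.65	2.63E-03	up	N/A
Prenylcysteine oxidase 1	XM_006268735.1	0.62	9.85E-03	up	C: lysosome
Formimidoyltransferase cyclodeaminase	XM_006260991.1	0.57	6.57E-03	up	C: cytosol
Uncharacterized LOC102563416	XR_363102.1	inf	4.73E-03	up	C: cytosol
Lysine (K)-specific demethylase 6B	XM_006271864.1	-1.42	2.63E-03	down	P: positive regulation of transcription from RNA polymerase II promoter
Protein Jumonji-like	XM_006270621.1	-1.32	2.63E-03	down	P: negative regulation of transcription from RNA polymerase II promoter
Protein Jumonji-like	XM_006270617.1	-1.32	2.63E-03	down	P: negative regulation of transcription from RNA polymerase II promoter
Cysteine and glycine-rich protein 2	XM_006269901.1	-1.31	2.63E-03	down	P: multicellular organismal development
Myeloid protein 1-like	XM_006275897.1	-1.30	2.63E-03	down	P: granulocyte differentiation
Protease, serine, 35	XM_006258407.1	-1.24	2.63E-03	down	C: extracellular region
ADAM metallopeptidase with thrombospondin type 1 motif, 15	XM_006262089.1	-1.24	2.63E-03	down	F: metalloendopeptidase activity
Cellular retinoic acid binding protein 2	XM_006275867.1	-1.18	2.63E-03	down	F: retinoic acid binding
Angiopoietin-like 1, transcript variant X2	XM_006267260.1	-1.18	2.63E-03	down	C: extracellular space
Transgelin	XM_006278069.1	-1.14	2.63E-03	down	F: protein binding, bridging
Dimethylaniline monooxygenase [N-oxide-forming] 3-like	XM_006259136.1	-1.06	2.63E-03	down	C: endoplasmic reticulum membrane
Elastin	XM_006267934.1	-1.05	2.63E-03	down	N/A
Uncharacterized LOC102575456, transcript variant X1	XR_363216.1	-1.03	2.63E-03	down	N/A
Hematopoietic prostaglandin D synthase	XM_006265263.1	-1.01	4.73E-03	down	C: cytoplasm
Hemoglobin subunit epsilon-like	XM_006259088.1	-0.95	2.63E-03	down	P: oxygen transport
Matrix-remodelling associated 5	XM_006277556.1	-0.94	2.63E-03	down	C: extracellular region
Epidermal retinol dehydrogenase 2-like	XM_006277024.1	-0.90	8.24E-03	down	P: retinal metabolic process
v-myb avian myeloblastosis viral oncogene homolog-like 2	XM_006276553.1	-0.82	2.63E-03	down	P: spindle assembly involved in mitosis
Protein Wnt-11-like, transcript variant X2	XM_006265079.1	-0.76	4.73E-03	down	P: positive regulation of apoptotic process
Thrombospondin 2, transcript variant X1	XM_006277394.1	-0.73	2.63E-03	down	C: basement membrane
Protein NEL-like	XM_006272242.1	-0.66	2.63E-03	down	F: kinase activity
Platelet-derived growth factor D-like	XM_006268644.1	-0.63	4.73E-03	down	P: regulation of peptidyl-tyrosine phosphorylation
RAS-like, family 11, member B	XM_006261252.1	-0.63	6.57E-03	down	P: small GTPase mediated signal transduction
Ubiquitin carboxyl-terminal esterase L1 (ubiquitin thiolesterase)	XM_006258484.1	-0.58	4.73E-03	down	F: cysteine-type endopeptidase activity
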