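gene	description	go_term
ASNS	Asparagine Synthetase	asparagine biosynthetic process
ALDH18A1	Aldehyde Dehydrogenase 18 Family Member A1	proline biosynthetic process
CAD	Carbamoyl-Phosphate Synthetase 2, Aspartate Transcarbamylase, And Dihydroorotase	'de novo' pyrimidine nucleobase biosynthetic process
CS	Citrate Synthase	tricarboxylic acid cycle
CTPS	CTP Synthase 1	'de novo' CTP biosynthetic process
CTPS2	CTP Synthase 2	'de novo' CTP biosynthetic process
DLD	Dermcidin	2-oxoglutarate metabolic process
DLST	Dihydrolipoamide S-Succinyltransferase	tricarboxylic acid cycle
GFPT1	Glutamine-Fructose-6-Phosphate Transaminase 1	UDP-N-acetylglucosamine biosynthetic process
GFPT2	Glutamine-Fructose-6-Phosphate Transaminase 2	UDP-N-acetylglucosamine biosynthetic process
GLUL	Glutamate-Ammonia Ligase	glutamine biosynthetic process
GLS	Glutaminase	glutamate biosynthetic process
GLS2	Glutaminase 2	glutamate biosynthetic process
OGDH	Oxoglutarate Dehydrogenase	tricarboxylic acid cycle
GGDHL	Oxoglutarate Dehydrogenase-like	tricarboxylic acid cycle
PFAS	Phosphoribosylformylglycinamidine Synthase	'de novo' IMP biosynthetic process
PPAT	Phosphoribosyl Pyrophosphate Amidotransferase	'de novo' IMP biosynthetic process
PSAT1	Phosphoserine Aminotransferase 1	'de novo' IMP biosynthetic process
GCLC	Glutamate-Cysteine Ligase Catalytic Subunit	glutathione biosynthetic process
GCLM	Glutamate-Cysteine Ligase Modifier Subunit	glutathione biosynthetic process
GSS	Glutathione Synthetase	glutathione biosynthetic process
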