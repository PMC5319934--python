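# Curated drug-like scaffold templates for the synthetic fixture generator.
# Each line: SMILES template with {0}/{1} substitution sites <TAB> name.
# Sites are filled with small substituent branches, e.g. "(C)", "(F)" or "".
O=C(Nc1ccc{0}cc1)c1ccc{1}cc1	benzanilide
O=S(=O)(Nc1ccc{0}cc1)c1ccc{1}cc1	diaryl-sulfonamide
O=C(Nc1ccc{0}cc1)C1CCN(Cc2ccc{1}cc2)CC1	benzylpiperidine-amide
c1cc{0}ccc1-c1nc2ccc{1}cc2[nH]1	2-arylbenzimidazole
O=C(c1ccc{0}cc1)N1CCN(c2ccc{1}cc2)CC1	arylpiperazine-benzamide
c1ccc2c(c1)[nH]c1ccc{0}c{1}c12	carbazole
O=C(N1CCC{0}CC1)c1ccc{1}cc1	piperidine-benzamide
c1cnc{0}nc1Nc1ccc{1}cc1	anilinopyrimidine
O=c1[nH]c2ccc{0}cc2n1Cc1ccc{1}cc1	benzylbenzimidazolone
COc1cc{0}ccc1OCCN1CCC(c2ccc{1}cc2)CC1	aryloxyethyl-piperidine
c1cc{0}cc{1}c1CN1CCN(c2ncccn2)CC1	benzylpiperazine-pyrimidine
O=C(O)c1ccc{0}cc1Oc1ccc{1}cc1	phenoxybenzoic-acid
N#Cc1cc{0}c{1}cc1Nc1ncnc2[nH]cnc12	purinylaniline
O=C1CC(c2ccc{0}cc2)Cc2cc{1}ccc21	aryl-tetralone
c1ccc2oc(-c3ccc{0}cc3)c{1}c2c1	2-arylbenzofuran
c1ccc2[nH]c(-c3ccc{0}cc3)c{1}c2c1	2-arylindole
O=C(Nc1ccc{0}cc1)c1ccc{1}s1	thiophene-carboxanilide
O=C(Nc1ccc{0}cc1)c1ccnc2ccc{1}cc12	quinoline-carboxanilide
c1cc{0}ccc1-n1ccc{1}n1	N-arylpyrazole
O=C(N1CCOCC1)c1cc{0}cc{1}c1	morpholino-benzamide
O=C(Nc1ccc{0}cc1)c1ccc{1}nc1	pyridine-carboxanilide
c1cc{0}ccc1-c1ccc{1}cc1	biphenyl
O=c1cc(-c2ccc{0}cc2)oc2cc{1}ccc12	flavone
O=C(Nc1ccc{0}cc1)Nc1ccc{1}cc1	diarylurea
c1cc{0}ccc1-c1nc2ccc{1}cc2s1	2-arylbenzothiazole
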