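# Substrate catalog: CAZy families, EC numbers, sulfatase S1 subfamilies and
# mannitol-pathway gene symbols mapped to dietary substrates of a macroalgae-
# feeding herbivore gut (brown algae: alginate, laminarin, FCSP, mannitol;
# red algae: carrageenan, agarose, starch; derived galactans; sulfate removal).
# Reconstructed curation covering this package's substrate scope only; not a
# mirror of the live CAZy/SulfAtlas databases.
# weight_class: HMW = endo-acting / polymer-cleaving, LMW = exo-acting /
# oligomer-consuming, NA = not applicable (binding modules, sulfatases,
# pathway genes). dedicated: 1 = unambiguous for a single substrate.
key	key_type	substrates	weight_class	dedicated	enzyme_label
PL6	family	alginate	HMW	1	guluronate-specific alginate lyase
PL34	family	alginate	HMW	1	mannuronate-specific alginate lyase
PL38	family	alginate	HMW	1	mannuronate-specific alginate lyase
PL17	family	alginate	LMW	1	oligo-alginate lyase
GH16	family	laminarin,agarose	HMW	0	endo-1,3(4)-beta-glucanase / beta-agarase
GH30	family	laminarin,FCSP	HMW	0	glucan endo-1,6-beta-glucosidase / alpha-fucosidase
GH17	family	laminarin	HMW	1	glucan endo-1,3-beta-D-glucosidase
GH158	family	laminarin	HMW	1	glucan endo-1,3-beta-D-glucosidase
GH149	family	laminarin	LMW	1	beta-1,3-glucan phosphorylase
GH1	family	laminarin	LMW	1	beta-glucosidase
GH3	family	laminarin	LMW	1	beta-glucosidase
GH29	family	FCSP	HMW	1	alpha-L-fucosidase
GH141	family	FCSP	HMW	1	alpha-L-fucosidase
GH151	family	FCSP	LMW	1	alpha-L-fucosidase
GH95	family	FCSP	LMW	1	alpha-L-fucosidase
GH150	family	carrageenan	HMW	1	lambda-carrageenase
GH82	family	carrageenan	HMW	1	iota-carrageenase
GH86	family	agarose	HMW	1	beta-agarase
GH50	family	agarose	HMW	1	beta-agarase
GH2	family	galactan	LMW	1	beta-galactosidase
GH35	family	galactan	LMW	1	beta-galactosidase
GH36	family	galactan	LMW	1	alpha-galactosidase
GH110	family	galactan	LMW	1	alpha-galactosidase
GH13	family	starch	HMW	0	alpha-amylase / pullulanase
GH57	family	starch	HMW	1	alpha-amylase
GH77	family	starch	LMW	1	4-alpha-glucanotransferase
GH133	family	starch	LMW	1	amylo-alpha-1,6-glucosidase
GH31	family	starch	LMW	1	alpha-glucosidase
CBM4	family	-	NA	0	carbohydrate-binding module
CBM6	family	-	NA	0	carbohydrate-binding module
CBM32	family	-	NA	0	carbohydrate-binding module
CBM48	family	-	NA	0	carbohydrate-binding module
GT2	family	-	NA	0	glycosyltransferase
GT4	family	-	NA	0	glycosyltransferase
CE1	family	-	NA	0	carbohydrate esterase
CE6	family	-	NA	0	carbohydrate esterase
CE10	family	-	NA	0	carbohydrate esterase
AA3	family	-	NA	0	auxiliary activity oxidoreductase
S1_15	s1	FCSP,sulfate_removal	NA	0	FCSP C2/C3 sulfatase
S1_16	s1	FCSP,sulfate_removal	NA	0	FCSP C2/C3 sulfatase
S1_17	s1	FCSP,carrageenan,sulfate_removal	NA	0	FCSP C4 / iota-carrageenan C2 sulfatase
S1_25	s1	FCSP,sulfate_removal	NA	0	fucose C3 exo-sulfatase
S1_7	s1	carrageenan,sulfate_removal	NA	0	kappa/iota-carrageenan G4S sulfatase
S1_19	s1	carrageenan,sulfate_removal	NA	0	kappa/iota-carrageenan G4S sulfatase
S1_8	s1	carrageenan,sulfate_removal	NA	0	lambda-carrageenan C2 sulfatase
4.2.2.11	ec	alginate	HMW	1	guluronate-specific alginate lyase
4.2.2.3	ec	alginate	HMW	1	mannuronate-specific alginate lyase
4.2.2.26	ec	alginate	LMW	1	oligo-alginate lyase
3.2.1.75	ec	laminarin	HMW	1	glucan endo-1,6-beta-glucosidase
3.2.1.39	ec	laminarin	HMW	1	glucan endo-1,3-beta-D-glucosidase
3.2.1.6	ec	laminarin	HMW	1	endo-1,3(4)-beta-glucanase
3.2.1.21	ec	laminarin	LMW	1	beta-glucosidase
3.2.1.51	ec	FCSP	HMW	1	alpha-L-fucosidase
3.2.1.83	ec	carrageenan	HMW	1	kappa-carrageenase
3.2.1.157	ec	carrageenan	HMW	1	iota-carrageenase
3.2.1.162	ec	carrageenan	HMW	1	lambda-carrageenase
3.2.1.81	ec	agarose	HMW	1	beta-agarase
3.2.1.23	ec	galactan	LMW	1	beta-galactosidase
3.2.1.22	ec	galactan	LMW	1	alpha-galactosidase
3.2.1.1	ec	starch	HMW	1	alpha-amylase
3.2.1.41	ec	starch	HMW	1	pullulanase
3.2.1.20	ec	starch	LMW	1	alpha-glucosidase
m2dh	gene	mannitol	NA	1	mannitol 2-dehydrogenase
fructokinase	gene	mannitol	NA	1	fructokinase
m1pdh	gene	mannitol	NA	1	mannitol-1-phosphate 5-dehydrogenase
pts_mannitol	gene	mannitol	NA	1	mannitol phosphotransferase system component
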