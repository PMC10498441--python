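template_id	reaction_name	smirks	n_reactants
T001	amide coupling	[C:1](=[O:2])[N;!$(N-[O,N]):3]>>[C:1](=[O:2])[OH1].[N:3]	2
T002	ester formation	[C:1](=[O:2])[O;!$([OH]):3][C:4]>>[C:1](=[O:2])[OH1].[O:3][C:4]	2
T003	N-alkylation	[N;!$(N~[!#6;!#1]);!$(N-C=[O,S,N]):1][CH2:2][c:3]>>[N:1].Br[CH2:2][c:3]	2
T004	Williamson ether	[C;!$(C=O):1][O:2][CH2:3][c:4]>>[C;!$(C=O):1][OH1:2].Br[CH2:3][c:4]	2
T005	reductive amination	[N;!$(N~[!#6;!#1]);!$(N-C=[O,S,N]):1][CH2:2][C:3]>>[N:1].[C:3][CH1:2]=O	2
T006	Suzuki coupling	[c:1]-[c:2]>>[c:1]Br.[c:2]B(O)O	2
T007	Buchwald-Hartwig amination	[c:1]-[N;!$(N=O);!$(N-C=[O,S,N]):2]>>[c:1]Br.[N:2]	2
T008	sulfonamide formation	[S:1](=[O:2])(=[O:3])[N:4]>>[S:1](=[O:2])(=[O:3])Cl.[N:4]	2
T009	urea formation	[N:1][C:2](=[O:3])[NH1:4]>>[N:1].[C:2](=[O:3])=[N:4]	2
T010	Boc protection	[N:1][C:2](=[O:3])[O:4]C(C)(C)C>>[N:1].CC(C)(C)OC(=O)[O:4][C:2](=[O:3])OC(C)(C)C	2
T011	nitro reduction	[NH2:1][c:2]>>[O-][N+:1](=O)[c:2]	1
T012	ketone reduction	[OH1:1][CH1:2]([#6:3])[#6:4]>>[O:1]=[C:2]([#6:3])[#6:4]	1
T013	nitrile hydrolysis	[C:1](=O)[OH1]>>[C:1]#N	1
T014	nitrile alkylation	[C:1][C;+0:2]#[N:3]>>[C:1]Br.[C-:2]#[N:3]	2
T015	Sonogashira coupling	[c:1][C:2]#[C:3]>>[c:1]Br.[CH1:2]#[C:3]	2
T016	Grignard addition	[#6:1][C:2]([OH1:3])([#6:4])[#6:5]>>[#6:1][Mg]Br.[#6:4][C:2](=[O:3])[#6:5]	2
T017	aldol condensation	[C:1](=[O:2])[C:3]=[C:4][c:5]>>[C:1](=[O:2])[CH2:3].[c:5][CH1:4]=O	2
T018	epoxide aminolysis	[N;!$(N~[!#6;!#1]);!$(N-C=[O,S,N]):1][C:2][C:3][OH1:4]>>[N:1].[C:2]1[C:3][O:4]1	2
T019	S-alkylation	[S;X2:1][CH2:2][c:3]>>[S:1].Br[CH2:2][c:3]	2
T020	carbamate formation	[N:1][C:2](=[O:3])[O:4][C:5]>>[N:1].Cl[C:2](=[O:3])[O:4][C:5]	2
T021	SNAr amination	[n:1]1[c:2][c:3][c:4][c:5][c:6]1-[N;!$(N=O);!$(N-C=[O,S,N]):7]>>[n:1]1[c:2][c:3][c:4][c:5][c:6]1Cl.[N:7]	2
T022	ester aminolysis	[C:1](=[O:2])[N;!$(N-[O,N]):3]>>[C:1](=[O:2])OC.[N:3]	2
T023	aryl bromination	[c:1]Br>>[cH1:1]	1
T024	benzylic oxidation	[c:1][C:2](=[O:3])[OH1]>>[c:1][CH3:2]	1
T025	alkene hydrogenation	[#6:1][CH2:2][CH2:3][#6:4]>>[#6:1][CH1:2]=[CH1:3][#6:4]	1
T026	imine formation	[C:1]=[N:2][C:3]>>[C:1]=O.[N:2][C:3]	2
T027	Fischer esterification (phenolic)	[C:1](=[O:2])[O:3][c:4]>>[C:1](=[O:2])[OH1].[O:3][c:4]	2
T028	amide N-methylation	[C:1](=[O:2])[N:3][CH3:4]>>[C:1](=[O:2])[NH1:3].I[CH3:4]	2
T029	phenol O-benzylation	[c:1][O:2][CH2:3][c:4]>>[c:1][OH1:2].Br[CH2:3][c:4]	2
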