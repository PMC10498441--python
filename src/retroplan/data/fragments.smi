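# fragment pool: small purchasable-grade building blocks, one SMILES per line
CC(=O)O
CCC(=O)O
OC(=O)c1ccccc1
OC(=O)c1ccc(C)cc1
OC(=O)c1ccc(F)cc1
OC(=O)C1CC1
OC(=O)c1ccc(O)cc1
CC(C)C(=O)O
OC(=O)c1ccncc1
OC(=O)Cc1ccccc1
Nc1ccccc1
CNc1ccccc1
CCN
NCc1ccccc1
C1CCNC1
C1CCNCC1
Nc1ccc(C)cc1
CN
NCCc1ccccc1
Nc1ccc(F)cc1
CCNCC
NC1CCCCC1
CCO
CC(C)O
OCc1ccccc1
Oc1ccccc1
OCCc1ccccc1
Oc1ccc(C)cc1
CO
OC1CCCCC1
Brc1ccccc1
Brc1ccc(C)cc1
Brc1ccc(F)cc1
Brc1ccncc1
Brc1ccc(OC)cc1
BrCc1ccccc1
BrCc1ccc(C)cc1
BrCc1ccc(F)cc1
OB(O)c1ccccc1
OB(O)c1ccc(C)cc1
OB(O)c1ccc(F)cc1
CC=O
O=Cc1ccccc1
O=Cc1ccc(C)cc1
CC(C)=O
CC(=O)c1ccccc1
O=C1CCCCC1
CCC(C)=O
O=Cc1ccc(F)cc1
Cc1ccc(S(=O)(=O)Cl)cc1
CS(=O)(=O)Cl
O=S(=O)(Cl)c1ccccc1
O=C=Nc1ccccc1
CCN=C=O
O=C=NC1CCCCC1
CC(C)(C)OC(=O)OC(=O)OC(C)(C)C
O=[N+]([O-])c1ccccc1
Cc1ccc([N+](=O)[O-])cc1
O=[N+]([O-])c1ccc(F)cc1
[C-]#N
N#Cc1ccccc1
CCC#N
C#Cc1ccccc1
C#CCC
C#CC1CCCCC1
C[Mg]Br
CC[Mg]Br
Br[Mg]c1ccccc1
CC(=O)OC
COC(=O)c1ccccc1
CCOC(=O)C
COC(=O)Cc1ccccc1
C1CO1
CC1CO1
c1ccccc1C1CO1
SCc1ccccc1
Sc1ccccc1
CCS
ClC(=O)OCC
ClC(=O)OCc1ccccc1
Clc1ccccn1
Clc1ccc(C)cn1
Cc1ccnc(Cl)c1
CC=CC
CCC=CCC
c1ccccc1C=CC
Cc1ccccc1
Cc1ccc(F)cc1
Cc1ccc(OC)cc1
CCBr
CCCBr
BrCCc1ccccc1
CC(C)Br
CI
CC(=O)Nc1ccccc1
O=C(Nc1ccccc1)c1ccccc1
O=[N+]([O-])c1ccc(OC)cc1
O=[N+]([O-])c1ccccn1
O=[N+]([O-])c1ccc(Cl)cc1
N#Cc1ccc(C)cc1
N#CCc1ccccc1
N#Cc1ccc(F)cc1
CCCC#N
CCC(=O)c1ccccc1
CC(=O)C1CC1
O=C1CCCC1
CC(=O)NCc1ccccc1
O=C(NC1CCCCC1)C
CCC(=O)Nc1ccccc1
CC(=O)Nc1ccc(C)cc1
CCC=CC
CC=CCc1ccccc1
C(=C/c1ccccc1)\c1ccccc1
c1ccc2ccccc2c1
Cc1cccc(C)c1
COc1ccccc1
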