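ligand,subunits,pathway,category
WNT5A,FZD3;LRP6,Wnt,secreted
WNT7B,FZD7;LRP5,Wnt,secreted
WNT3,FZD1;LRP6,Wnt,secreted
RSPO2,LGR5,Wnt,secreted
EFNA5,EPHA4,ephrin,contact
EFNA3,EPHA3,ephrin,contact
EFNB2,EPHB1,ephrin,contact
EFNB3,EPHB6,ephrin,contact
EFNA1,EPHA7,ephrin,contact
SEMA3A,NRP1;PLXNA4,semaphorin,secreted
SEMA3E,PLXND1,semaphorin,secreted
SEMA4D,PLXNB1,semaphorin,contact
SEMA5A,PLXNA1,semaphorin,contact
SEMA6A,PLXNA2,semaphorin,contact
TGFB1,TGFBR1;TGFBR2,TGFB,secreted
TGFB2,TGFBR1;TGFBR2,TGFB,secreted
TGFB3,TGFBR1;TGFBR2,TGFB,secreted
GDF11,ACVR1B;ACVR2A,TGFB,secreted
SHH,PTCH1;SMO,SHH,secreted
DHH,PTCH1;SMO,SHH,secreted
DLL1,NOTCH1,Notch,contact
DLL3,NOTCH2,Notch,contact
JAG1,NOTCH1,Notch,contact
JAG2,NOTCH3,Notch,contact
BMP2,BMPR1A;BMPR2,BMP,secreted
BMP4,BMPR1A;BMPR2,BMP,secreted
BMP6,BMPR1B;BMPR2,BMP,secreted
BMP7,ACVR1;BMPR2,BMP,secreted
NRG1,ERBB3;ERBB2,neuregulin,secreted
NRG3,ERBB4,neuregulin,secreted
BDNF,NTRK2,neurotrophin,secreted
NTF3,NTRK3,neurotrophin,secreted
NGF,NTRK1,neurotrophin,secreted
FGF1,FGFR1,FGF,secreted
FGF2,FGFR2,FGF,secreted
FGF9,FGFR3,FGF,secreted
IGF1,IGF1R,IGF,secreted
IGF2,IGF2R,IGF,secreted
PDGFA,PDGFRA,PDGF,secreted
PDGFB,PDGFRB,PDGF,secreted
VEGFA,FLT1,VEGF,secreted
ANGPT1,TEK,angiopoietin,secreted
CX3CL1,CX3CR1,chemokine,secreted
CXCL12,CXCR4,chemokine,secreted
IL34,CSF1R,cytokine,secreted
TNF,TNFRSF1A,cytokine,secreted
NLGN1,NRXN1,adhesion,contact
NCAM1,NCAM1,adhesion,contact
CADM1,CADM1,adhesion,contact
PTN,PTPRZ1,PTN,secreted
MDK,SDC1,PTN,secreted
SLIT2,ROBO1;ROBO2,slit,secreted
NTN1,DCC,netrin,secreted
RELN,LRP8;VLDLR,reelin,secreted
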