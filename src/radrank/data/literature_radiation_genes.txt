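# Radiation-response biomarkers compiled from a manual literature survey:
# 221 unique gene symbols plus 4 protein complexes (COMPLEX: lines).
ABCA1
ABL1
ACTA2
AEN
AKR1B1
AKT1
ALAD
ANXA1
APEX1
APOE
AR
ATF3
ATM
BAD
BAK1
BAX
BAZ1B
BBC3
BCL2
BCL2L1
BIRC5
BRCA1
BRCA2
BTG2
CAT
CAV1
CCNB1
CCND1
CCNE1
CCNG1
CD24
CD40
CD68
CD69
CD70
CD83
CDC20
CDC6
CDH2
CDK1
CDK2
CDKN1A
CDKN2A
CHEK1
CLIC1
CRYAB
CSNK2A2
CXCR4
CYP2D6
DCN
DDB2
DDR1
DDR2
DDX17
DRAP1
DUSP8
EGFR
EGR1
EGR4
EI24
EIF2AK3
EPDR1
ERBB2
ERCC1
ERCC2
ERCC4
ERCC5
FAS
FASLG
FDXR
FGF1
FGF2
GADD45A
GBP1
GDF15
GFER
GRAP
GSTA1
GSTM1
GSTP1
GSTT1
H2AFX
HDAC1
HERC2
HSP90AB1
HSP90B1
HSPB1
HUS1
ICAM2
ID3
IER5
IFNG
IGF1R
IGFBP3
IL12RB2
IL17A
ILK
IRF1
JUN
KRAS
LIG1
LIG3
LIG4
LOX
LSM7
MAD2L2
MAP3K7
MC1R
MCL1
MCM2
MDC1
MDM2
MGMT
MLH1
MMP2
MMP9
MPO
MR1
MRE11A
MRPL23
MSH2
MTHFR
MTOR
MYC
NBN
NEIL1
NEK2
NFKB1
NNMT
NONO
NOS3
NOX4
NUDT1
OGG1
PAH
PAK6
PARP1
PCNA
PER3
PHLPP2
PHPT1
PIK3CA
PIM2
PLK2
PLK3
PMS2
POLB
POLQ
PPA1
PPM1D
PRDX1
PRDX4
PRKCB
PRKCZ
PRKDC
PROCR
PROM1
PSMB4
PSMD1
PTCH1
PTEN
PTGS2
PTTG1
RAD21
RAD23B
RAD50
RAD51
RAD54L
RAD9A
RALBP1
RELA
RND1
RRM2
RRM2B
S100A11
SAG
SART1
SEC22B
SEPHS1
SERPINA3
SERPINE1
SESN1
SIRT1
SMPD1
SOD1
SOD2
SRC
SRF
STAT1
STAT3
SUMO1
TGFB1
TNF
TNFRSF10B
TNFRSF1A
TNFSF10
TNFSF9
TOB1
TOP2A
TOR1AIP1
TP53
TP63
TPP2
TRAF2
TRAF4
TXN
TXNRD1
UBB
UHRF1
UIMC1
VEGFA
WRN
WT1
XIAP
XPC
XRCC1
XRCC2
XRCC3
XRCC4
XRCC5
XRCC6
COMPLEX:DNA-PK
COMPLEX:HSP70
COMPLEX:MRN(95)
COMPLEX:RAS
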