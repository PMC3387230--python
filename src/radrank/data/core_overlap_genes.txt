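# 20 genes shared by the literature survey and both microarray datasets.
ACTA2
BAX
BBC3
BTG2
CCNG1
CD70
CDKN1A
DDB2
EI24
FDXR
GADD45A
MDM2
MR1
MYC
PCNA
PLK2
PLK3
PPM1D
TNFRSF10B
XPC
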