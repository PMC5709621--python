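# Human cell-cycle gene symbols (GO:0007049-derived convenience fixture)
CDK1
CDK2
CDK4
CDK6
CDK7
CDK9
CCNA2
CCNB1
CCNB2
CCND1
CCND2
CCND3
CCNE1
CCNE2
CCNF
CCNH
CCNT1
CDC6
CDC7
CDC20
CDC25A
CDC25B
CDC25C
CDC45
CDC27
CDC16
CDC23
CDC26
CDC14A
CDC14B
CDKN1A
CDKN1B
CDKN1C
CDKN2A
CDKN2B
CDKN2C
CDKN2D
CDKN3
MCM2
MCM3
MCM4
MCM5
MCM6
MCM7
ORC1
ORC2
ORC3
ORC4
ORC5
ORC6
E2F1
E2F2
E2F3
E2F4
E2F5
E2F6
E2F7
E2F8
RB1
RBL1
RBL2
TP53
MDM2
ATM
ATR
CHEK1
CHEK2
WEE1
PKMYT1
PLK1
PLK2
PLK3
PLK4
AURKA
AURKB
AURKC
BUB1
BUB1B
BUB3
MAD1L1
MAD2L1
MAD2L2
TTK
CENPA
CENPE
CENPF
INCENP
BIRC5
CDCA2
CDCA3
CDCA5
CDCA8
SGO1
SGO2
ESPL1
PTTG1
SMC1A
SMC1B
SMC2
SMC3
SMC4
STAG1
STAG2
RAD21
NCAPD2
NCAPD3
NCAPG
NCAPG2
NCAPH
NCAPH2
TOP2A
KIF11
KIF15
KIF20A
KIF23
KIF2C
KIFC1
PRC1
ANLN
ECT2
RACGAP1
MKI67
FOXM1
MYBL2
LIN9
LIN37
LIN52
LIN54
RBBP4
TFDP1
TFDP2
GADD45A
GADD45B
GADD45G
PCNA
RRM1
RRM2
TYMS
TK1
DHFR
POLA1
POLD1
POLE
PRIM1
FEN1
LIG1
RFC1
RFC2
RFC3
RFC4
RFC5
RPA1
RPA2
RPA3
GINS1
GINS2
GINS3
GINS4
CDT1
GMNN
DBF4
CLSPN
TIMELESS
TIPIN
RAD51
BRCA1
BRCA2
BARD1
EXO1
BLM
WRN
RECQL4
FBXO5
SKP2
FZR1
ANAPC1
ANAPC2
ANAPC4
ANAPC5
ANAPC7
ANAPC10
ANAPC11
UBE2C
UBE2S
PSMA3
CKS1B
CKS2
ZWINT
ZW10
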