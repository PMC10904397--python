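# Synthetic stand-in for the curated 85-gene pediatric CPS (Category 1) panel.
# Partition follows the published counts: AD n=59 (9 gain-of-function), AR n=23, XLR n=3;
# penetrance/de-novo classes are illustrative, not curated values.
gene,category,moi,mechanism,cancer_only,penetrance_class,de_novo_class
ALK,pCPS_cat1,AD,GoF,False,high,high
APC,pCPS_cat1,AD,LoF,True,very_high,high
ATM,pCPS_cat1,AR,LoF,False,low,unknown
AXIN2,pCPS_cat1,AD,LoF,False,unknown,unknown
BAP1,pCPS_cat1,AD,LoF,True,high,very_high
BCOR,pCPS_cat1,XLR,LoF,False,unknown,unknown
BLM,pCPS_cat1,AR,LoF,False,unknown,unknown
BMPR1A,pCPS_cat1,AD,LoF,False,unknown,unknown
BRAF,pCPS_cat1,AD,GoF,False,low,low
BRCA2,pCPS_cat1,AR,LoF,False,very_low,unknown
CDC73,pCPS_cat1,AD,LoF,False,unknown,unknown
CDK4,pCPS_cat1,AD,GoF,False,very_high,unknown
CDKN2A,pCPS_cat1,AD,LoF,True,low,low
CEBPA,pCPS_cat1,AD,LoF,False,unknown,unknown
CREBBP,pCPS_cat1,AD,LoF,False,high,very_high
CTR9,pCPS_cat1,AD,LoF,True,very_low,very_low
DICER1,pCPS_cat1,AD,LoF,True,high,high
DIS3L2,pCPS_cat1,AR,LoF,False,unknown,unknown
ELP1,pCPS_cat1,AD,LoF,True,low,very_low
EP300,pCPS_cat1,AD,LoF,False,low,low
ETV6,pCPS_cat1,AD,LoF,False,unknown,unknown
FANCA,pCPS_cat1,AR,LoF,False,low,unknown
FANCB,pCPS_cat1,XLR,LoF,False,unknown,unknown
FANCC,pCPS_cat1,AR,LoF,False,unknown,unknown
FANCD2,pCPS_cat1,AR,LoF,False,very_low,unknown
FANCE,pCPS_cat1,AR,LoF,False,low,unknown
FANCF,pCPS_cat1,AR,LoF,False,unknown,unknown
FANCG,pCPS_cat1,AR,LoF,False,very_low,unknown
FANCI,pCPS_cat1,AR,LoF,False,low,unknown
FANCL,pCPS_cat1,AR,LoF,False,unknown,unknown
FBXW7,pCPS_cat1,AD,LoF,True,very_high,high
FH,pCPS_cat1,AD,LoF,False,unknown,unknown
GATA2,pCPS_cat1,AD,LoF,False,unknown,unknown
GPC3,pCPS_cat1,XLR,LoF,False,unknown,unknown
GPR161,pCPS_cat1,AD,LoF,True,high,very_high
HRAS,pCPS_cat1,AD,GoF,False,very_high,unknown
KRAS,pCPS_cat1,AD,GoF,False,low,low
LZTR1,pCPS_cat1,AD,LoF,False,unknown,unknown
MAX,pCPS_cat1,AD,LoF,False,high,very_high
MEN1,pCPS_cat1,AD,LoF,False,unknown,unknown
MET,pCPS_cat1,AD,GoF,False,low,low
MLH1,pCPS_cat1,AR,LoF,False,unknown,unknown
MSH2,pCPS_cat1,AR,LoF,False,low,unknown
MSH6,pCPS_cat1,AR,LoF,False,very_low,unknown
MUTYH,pCPS_cat1,AR,LoF,False,low,unknown
NBN,pCPS_cat1,AR,LoF,False,very_low,unknown
NF1,pCPS_cat1,AD,LoF,False,very_low,very_low
NF2,pCPS_cat1,AD,LoF,False,high,high
PALB2,pCPS_cat1,AR,LoF,False,low,unknown
PAX5,pCPS_cat1,AD,LoF,True,low,low
PHOX2B,pCPS_cat1,AD,LoF,False,very_high,high
PIK3CA,pCPS_cat1,AD,GoF,False,high,high
PMS2,pCPS_cat1,AR,LoF,False,low,unknown
POT1,pCPS_cat1,AD,LoF,False,unknown,unknown
PTCH1,pCPS_cat1,AD,LoF,False,very_high,high
PTEN,pCPS_cat1,AD,LoF,False,unknown,unknown
PTPN11,pCPS_cat1,AD,GoF,False,high,high
RB1,pCPS_cat1,AD,LoF,True,very_low,very_low
RECQL4,pCPS_cat1,AR,LoF,False,very_low,unknown
REST,pCPS_cat1,AD,LoF,True,high,high
RET,pCPS_cat1,AD,GoF,False,very_high,unknown
RMRP,pCPS_cat1,AR,LoF,False,very_low,unknown
RUNX1,pCPS_cat1,AD,LoF,False,unknown,unknown
SAMD9L,pCPS_cat1,AD,LoF,False,unknown,unknown
SDHA,pCPS_cat1,AD,LoF,False,low,low
SDHB,pCPS_cat1,AD,LoF,False,very_low,very_low
SDHC,pCPS_cat1,AD,LoF,False,high,high
SDHD,pCPS_cat1,AD,LoF,False,low,very_low
SMAD4,pCPS_cat1,AD,LoF,False,unknown,unknown
SMARCA4,pCPS_cat1,AD,LoF,True,low,very_low
SMARCB1,pCPS_cat1,AD,LoF,True,very_high,high
SMARCE1,pCPS_cat1,AD,LoF,True,high,very_high
SPRED1,pCPS_cat1,AD,LoF,False,unknown,unknown
STK11,pCPS_cat1,AD,LoF,False,unknown,unknown
SUFU,pCPS_cat1,AD,LoF,False,low,very_low
TMEM127,pCPS_cat1,AD,LoF,False,unknown,unknown
TP53,pCPS_cat1,AD,LoF,True,low,low
TRIM28,pCPS_cat1,AD,LoF,True,very_low,very_low
TRIP13,pCPS_cat1,AD,LoF,True,high,high
TSC1,pCPS_cat1,AD,LoF,False,high,very_high
TSC2,pCPS_cat1,AD,LoF,False,low,unknown
VHL,pCPS_cat1,AD,LoF,False,very_high,high
WRN,pCPS_cat1,AR,LoF,False,unknown,unknown
WT1,pCPS_cat1,AD,LoF,False,low,very_low
XPA,pCPS_cat1,AR,LoF,False,unknown,unknown
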