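gene,module
DNMT3A,dna_methylation
TET2,dna_methylation
IDH1,dna_methylation
IDH2,dna_methylation
ASXL1,chromatin_modifiers
ASXL2,chromatin_modifiers
EZH2,chromatin_modifiers
KDM5A,chromatin_modifiers
KDM6A,chromatin_modifiers
KMT2D,chromatin_modifiers
EP300,chromatin_modifiers
BCOR,chromatin_modifiers
BCORL1,chromatin_modifiers
PHF6,chromatin_modifiers
SRSF2,spliceosome
SF3B1,spliceosome
U2AF1,spliceosome
ZRSR2,spliceosome
DHX15,spliceosome
RAD21,cohesin
SMC1A,cohesin
SMC3,cohesin
STAG2,cohesin
RUNX1,myeloid_transcription_factors
ETV6,myeloid_transcription_factors
CEBPA,myeloid_transcription_factors
GATA1,myeloid_transcription_factors
GATA2,myeloid_transcription_factors
WT1,myeloid_transcription_factors
MYC,myeloid_transcription_factors
MGA,myeloid_transcription_factors
ZBTB7A,myeloid_transcription_factors
NPM1,npm1
FLT3,signaling
FLT3-ITD,signaling
FLT3-TKD,signaling
KIT,signaling
KRAS,signaling
NRAS,signaling
PTPN11,signaling
JAK2,signaling
CBL,signaling
CSF3R,signaling
NF1,signaling
CCND2,signaling
SETBP1,signaling
PIGA,signaling
TP53,tumor_suppressors
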