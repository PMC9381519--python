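# MDS-pattern mutation set used for the molecular secondary-AML flag.
# Edit freely; one gene symbol per line.
SRSF2
SF3B1
U2AF1
ZRSR2
ASXL1
EZH2
BCOR
STAG2
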