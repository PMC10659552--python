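# Default gene -> pathway mapping for the 19-gene AML targeted panel.
# Edit or replace via configuration; genes not listed map to OTHER.
DNA_METHYLATION: [DNMT3A, IDH1, IDH2, TET2]
SIGNALING: [FLT3, NRAS, KRAS, PTPN11, KIT, JAK2]
NPM1: [NPM1]
TRANSCRIPTION_FACTOR: [RUNX1, WT1, GATA2, CEBPA]
SPLICING: [SF3B1, SRSF2, U2AF1]
CHROMATIN: [ASXL1, EZH2]
TP53: [TP53]
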