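panel,numerator,denominator
diagnostic,TNFRSF17,CD48
diagnostic,CD48,PRTN3
diagnostic,PRTN3,PLA2G7
diagnostic,PLA2G7,PDCD1LG2
diagnostic,PDCD1LG2,CCL7
diagnostic,CCL7,SLAMF6
diagnostic,SLAMF6,TLR4_LY96
diagnostic,TLR4_LY96,CSF3
diagnostic,CSF3,CDKN1B
diagnostic,CDKN1B,TNFRSF6B
diagnostic,TNFRSF6B,TNC
diagnostic,TNC,CRK
diagnostic,CRK,PGK1
diagnostic,PGK1,MAPK14
diagnostic,MAPK14,FLT4
diagnostic,FLT4,F9
diagnostic,F9,CXCL13
diagnostic,CXCL13,TNFRSF4
diagnostic,TNFRSF4,DCTPP1
diagnostic,DCTPP1,MMP7
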