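panel,numerator,denominator
progms,EDA2R,SELL
progms,CFD,SERPING1
progms,ICOSLG,LTA_LTB
progms,IL22,INHBA
progms,GP6,EDAR
progms,PRTN3,LILRB2
progms,STX1A,JAM3
progms,EPHA5,GZMA
progms,NTRK3,IL10
progms,CLEC1B,TYRO3
progms,BOC,ETHE1
progms,UNC5C,RGMA
progms,EDA2R,CFD
progms,SELL,SERPING1
progms,CFD,ICOSLG
progms,SERPING1,LTA_LTB
progms,ICOSLG,IL22
progms,LTA_LTB,INHBA
progms,IL22,GP6
progms,INHBA,EDAR
progms,GP6,PRTN3
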