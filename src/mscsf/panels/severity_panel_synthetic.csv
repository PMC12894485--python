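panel,numerator,denominator
severity,SEVP001,SEVP002
severity,SEVP003,SEVP004
severity,SEVP005,SEVP006
severity,SEVP007,SEVP008
severity,SEVP009,SEVP010
severity,SEVP011,SEVP012
severity,SEVP013,SEVP014
severity,SEVP015,SEVP016
severity,SEVP017,SEVP018
severity,SEVP019,SEVP020
severity,SEVP021,SEVP022
severity,SEVP023,SEVP024
severity,SEVP025,SEVP026
severity,SEVP027,SEVP028
severity,SEVP029,SEVP030
severity,SEVP031,SEVP032
severity,SEVP033,SEVP034
severity,SEVP035,SEVP036
severity,SEVP037,SEVP038
severity,SEVP039,SEVP040
severity,SEVP041,SEVP042
severity,SEVP043,SEVP044
severity,SEVP045,SEVP046
severity,SEVP047,SEVP048
severity,SEVP049,SEVP050
severity,SEVP051,SEVP052
severity,SEVP053,SEVP054
severity,SEVP055,SEVP056
severity,SEVP057,SEVP058
severity,SEVP059,SEVP060
severity,SEVP061,SEVP062
severity,SEVP063,SEVP064
severity,SEVP065,SEVP066
severity,SEVP067,SEVP068
severity,SEVP069,SEVP070
severity,SEVP071,SEVP072
severity,SEVP073,SEVP074
severity,SEVP075,SEVP001
severity,SEVP001,SEVP003
severity,SEVP002,SEVP004
severity,SEVP003,SEVP005
severity,SEVP004,SEVP006
severity,SEVP005,SEVP007
severity,SEVP006,SEVP008
severity,SEVP007,SEVP009
severity,SEVP008,SEVP010
severity,SEVP009,SEVP011
severity,SEVP010,SEVP012
severity,SEVP011,SEVP013
severity,SEVP012,SEVP014
severity,SEVP013,SEVP015
severity,SEVP014,SEVP016
severity,SEVP015,SEVP017
severity,SEVP016,SEVP018
severity,SEVP017,SEVP019
severity,SEVP018,SEVP020
severity,SEVP019,SEVP021
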