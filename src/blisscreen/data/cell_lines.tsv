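name	tissue	cells_per_well	doubling_time_h
A498	kidney cancer	972	66.8
AGS	gastric adenocarcinoma	800	20
COLO 205	colorectal cancer	3000	23.8
DU-145	prostate cancer	2100	32.3
MDA-MB-468	breast cancer	8100	62
SF-295	glioblastoma	1050	29.5
SW-620	colorectal cancer	3750	20.4
UACC-62	melanoma	945	31.3
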