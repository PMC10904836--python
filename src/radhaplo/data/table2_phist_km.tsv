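population	SCA-Copenhagen	SCA-Erken	SIB-Baikal	BAL-GulfOfFinland	BAL-Tvarminne	ANT-Highway	ANT-McNeil	ANT-Vereteno
SCA-Copenhagen	0	0.403	0.864	0.945	0.940	0.963	0.962	0.962
SCA-Erken	587	0	0.595	0.774	0.794	0.835	0.820	0.830
SIB-Baikal	5682	5122	0	0.961	0.948	0.968	0.962	0.963
BAL-GulfOfFinland	864	349	4819	0	-0.034	0.978	0.976	0.974
BAL-Tvarminne	785	259	4898	91	0	0.959	0.955	0.955
ANT-Highway	14769	15019	13586	14868	14906	0	0.002	0.514
ANT-McNeil	14779	15028	13591	14878	14915	9	0	0.539
ANT-Vereteno	14779	15028	13588	14878	14915	10	2.5	0
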