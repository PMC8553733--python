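# source: Kidd-lab sample accounting (sequenced individuals by study, HGDP overlap, inclusion in analyses)
population	this_study	previous_study	hgdp	included
Biaka	32	4	10	true
Masai	20	0	0	true
Sandawe	0	40	0	true
Zaramo	0	28	0	true
Chagga	0	45	0	true
Ethiopian Jews	31	0	0	true
Adygei	0	30	12	true
Khanty	45	0	0	true
Yakut	48	0	0	true
Atayal	36	0	0	true
Cambodians	23	0	0	true
Nasioi	23	0	0	true
Papuans, New Guinea	22	0	8	true
Micronesians	37	0	0	true
Pima, Mexico	35	0	0	true
Maya	25	0	2	true
Southern Tunisians	4	0	0	false
EuroAmericans	0	6	0	false
Chinese, Taiwan	0	2	0	false
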