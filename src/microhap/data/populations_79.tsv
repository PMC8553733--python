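# source: study population roster (79 populations, sample sizes, data source)
abbrev	name	world_region	sample_size	source
BIA	Biaka	Central Africa	46	KL,HGDP
GWD	Gambians	West Africa	113	1KG
MDK	Mandenka	West Africa	22	HGDP
MSL	Mende	West Africa	85	1KG
ESN	Esan	West Africa	99	1KG
YOR	Yoruba, Benin City	West Africa	22	HGDP
YRI	Yoruba, Ibadan	West Africa	108	1KG
LWK	Luhya, Kenya	East Africa	99	1KG
ZRM	Zaramo	East Africa	28	KL
CGA	Chagga	East Africa	45	KL
MAS	Masai, Tanzania	East Africa	20	KL
MKK	Masai, Kenya	East Africa	17	GA
SND	Sandawe	East Africa	40	KL
ACB	Afro-Caribbeans	East Africa	96	1KG
ASW	AfrAmer, Southwest USA	East Africa	61	1KG
ETJ	Ethiopian Jews	East Africa	31	KL
MZB	Mozabites	North Africa	27	HGDP
BDN	Bedouin	Southwest Asia	46	HGDP
DRZ	Druze	Southwest Asia	42	HGDP
PLS	Palestinians	Southwest Asia	46	HGDP
ADY	Adygei	Southwest Asia	42	KL,HGDP
SRD	Sardinians	Europe	28	HGDP
TSI	Tuscans	Europe	107	1KG
IBS	Iberians	Europe	107	1KG
BSQ	Basques, France	Europe	23	HGDP
ORC	Orcadians	Europe	15	HGDP
CEU	CEPH Europeans	Europe	99	1KG
GBR	Great Britain	Europe	91	1KG
FRN	French	Europe	28	HGDP
RUS	Russians	Europe	25	HGDP
FIN	Finns	Europe	99	1KG
KLS	Kalash, Pakistan	So Central Asia	22	HGDP
PTH	Pathans, Pakistan	So Central Asia	35	HGDP,GA
GJJ	Gujjar, Pakistan	So Central Asia	20	GA
BLC	Balochi, Pakistan	So Central Asia	24	HGDP
SNH	Sindhi, Pakistan	So Central Asia	24	HGDP
MKR	Makrani, Pakistan	So Central Asia	25	HGDP
BRH	Brahui, Pakistan	So Central Asia	25	HGDP
BRS	Burusho, Pakistan	So Central Asia	24	HGDP
PJL	Punjabi, Lahore	So Central Asia	96	1KG
GIH	Gujarati	So Central Asia	103	1KG
CNI	Urban Chennai	So Central Asia	34	GA
BGL	Urban Bangalore	So Central Asia	34	GA
ITU	Telugu	So Central Asia	102	1KG
STU	Tamil, SriLanka	So Central Asia	102	1KG
BEB	Bengali, Bangladesh	So Central Asia	86	1KG
LMB	Lambada, India	So Central Asia	17	GA
AGH	Agharia, India	So Central Asia	17	GA
MHR	Mahar, India	So Central Asia	19	GA
TOD	Toda, India	So Central Asia	20	GA
ORA	Oraon, India	So Central Asia	15	GA
KND	KondaReddy, India	So Central Asia	17	GA
BIR	Birhor, India	So Central Asia	20	GA
HZR	Hazara, Pakistan	So Central Asia	26	HGDP,GA
KTY	Khanty	East Asia	45	KL
MOG	Mog, India	East Asia	20	GA
BUR	Buryat	East Asia	87	GA
YAK	Yakut	East Asia	48	KL
KRE	Koreans	East Asia	150	GA
JPT	Japanese, Tokyo	East Asia	104	1KG
JPA	Japanese, Tokyo healthy controls	East Asia	30	GA
JPH	Japanese	East Asia	27	HGDP
CHB	HanChinese, Beijing	East Asia	103	1KG
HAN	HanChinese, HGDP	East Asia	43	HGDP
CHS	SouthernHanChinese	East Asia	105	1KG
CDX	Dai	East Asia	93	1KG
KHV	Vietnamese	East Asia	99	1KG
CBD	Cambodians	East Asia	23	KL
ATL	Atayal	East Asia	36	KL
ASN	Austronesians, Indonesia	Oceania	25	GA
ATI	Ati, Philippines	Oceania	21	GA
FLR	Flores, Rampasasa, Indonesia	Oceania	20	GA
AET	Aeta, Philippines	Oceania	29	GA
MCR	Micronesians	Oceania	37	KL
PNG	Papuans, NewGuinea	Oceania	30	KL,HGDP
NAS	Nasioi	Oceania	23	KL
PMM	Pima, Mexico	Americas	35	KL
MAY	Maya	Americas	27	KL,HGDP
PEL	Peruvians	Americas	85	1KG
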