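# Published in-silico screening table for the 82 released candidate peptides:
# toxicity (ToxinPred), allergenicity (AllergenFP) and water solubility
# (log S, SwissADME) as printed in the source screen. Ingested annotations;
# none of these values are computed by this package.
peptide	toxicity	allergen	log_s
AHD	Non	Allergen	1.52
CCP	Non	Allergen	1.45
CSK	Non	Allergen	2.28
HPG	Non	Allergen	1.02
IPG	Non	Allergen	0.46
IPP	Non	Allergen	-0.30
ISK	Non	Allergen	1.36
NSG	Non	Allergen	3.19
PPSG	Non	Allergen	1.30
SCL	Non	Allergen	1.05
SHPE	Non	Allergen	1.83
SPG	Non	Allergen	2.52
VKN	Non	Allergen	1.56
VPC	Non	Allergen	0.75
VPT	Non	Allergen	1.10
VWY	Non	Allergen	-2.00
WSSG	Non	Allergen	0.92
AG	Non	Non	1.82
AR	Non	Non	2.37
CD	Non	Non	1.80
CF	Non	Non	0.32
CHSG	Non	Non	1.93
CK	Non	Non	1.14
CL	Non	Non	0.13
CN	Non	Non	2.22
CPN	Non	Non	2.35
CR	Non	Non	1.71
CT	Non	Non	1.67
DPG	Non	Non	2.29
EVG	Non	Non	1.80
HCK	Non	Non	1.10
HG	Non	Non	1.44
HHG	Non	Non	1.18
HK	Non	Non	1.22
HR	Non	Non	1.50
IC	Non	Non	2.22
ICD	Non	Non	0.99
IG	Non	Non	0.96
IK	Non	Non	1.27
IL	Non	Non	0.25
IN	Non	Non	2.10
IR	Non	Non	1.54
IS	Non	Non	1.38
ISG	Non	Non	1.63
IT	Non	Non	1.26
KPG	Non	Non	1.46
LK	Non	Non	1.11
LR	Non	Non	1.37
PD	Non	Non	2.03
PG	Non	Non	1.76
PM	Non	Non	1.04
PRG	Non	Non	1.50
PS	Non	Non	2.25
PSR	Non	Non	2.67
SF	Non	Non	1.03
SG	Non	Non	2.45
SHT	Non	Non	2.01
SK	Non	Non	1.86
SL	Non	Non	0.84
SM	Non	Non	1.22
SN	Non	Non	2.93
SPGE	Non	Non	2.59
SPT	Non	Non	2.51
SR	Non	Non	2.12
ST	Non	Non	2.38
VCD	Non	Non	1.01
VCF	Non	Non	-0.48
VCPE	Non	Non	1.33
VK	Non	Non	1.52
VL	Non	Non	0.50
VM	Non	Non	0.88
VN	Non	Non	2.53
VPG	Non	Non	1.17
VR	Non	Non	1.78
VSG	Non	Non	2.27
VW	Non	Non	-0.77
VWK	Non	Non	-0.81
VY	Non	Non	0.25
WG	Non	Non	-0.11
WY	Non	Non	-1.29
HN	Non	Non	1.98
PT	Non	Non	1.89
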