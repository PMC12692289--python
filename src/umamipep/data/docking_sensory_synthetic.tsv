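# SYNTHETIC docking/sensory annotation fixture. The source study's docking
# energies (-CE, -CIE, kcal/mol) and sensory panel scores are external
# measurements that cannot be recomputed here; this fixture mirrors the
# reported pass/fail pattern only: 44 peptides carry docking annotations,
# 9 fail to dock (the reported failure set, with the printed "CHSC" mapped
# to the table peptide CHSG), 9 show both -CE and -CIE > 40 (the reported
# candidate set), and of those, 6 score > 5 on the 0-10 umami sensory scale
# (reported scores kept where printed: VY 7.01, IS 7.01, SM 4.91, HN 4.82,
# IT 4.82; other values are invented placeholders). Numeric values other
# than the five printed sensory scores are synthetic.
peptide	ce	cie	docking_failed	sensory_umami
CHSG			1
ICD			1
KPG			1
PRG			1
PSR			1
SHT			1
SPGE			1
SPT			1
VCPE			1
VY	47.3	46.0	0	7.01
VM	46.1	45.1	0	6.2
SL	45.0	44.2	0	5.8
SN	44.3	43.4	0	5.6
VN	43.2	42.5	0	5.5
IS	42.8	41.7	0	7.01
SM	43.9	41.2	0	4.91
HN	42.1	40.9	0	4.82
IT	41.5	40.6	0	4.82
CF	38.2	33.1	0
CT	36.4	31.8	0
DPG	41.9	38.6	0
EVG	39.7	36.2	0
HCK	34.8	29.5	0
HG	37.5	34.9	0
HHG	42.6	39.4	0
HK	33.9	28.7	0
HR	35.6	30.2	0
IG	38.8	35.7	0
ISG	40.9	37.3	0
PD	36.9	32.4	0
PG	31.2	27.6	0
PS	34.1	30.8	0
SF	39.3	36.8	0
SG	32.7	28.9	0
SK	35.2	31.5	0
SR	37.1	33.6	0
ST	38.6	34.2	0
VCD	40.4	37.9	0
VK	36.0	32.8	0
VL	39.9	38.1	0
VPG	41.1	39.8	0
VR	34.5	29.9	0
VSG	43.7	39.1	0
PT	33.4	28.2	0
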