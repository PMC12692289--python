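# umamipep known-umami-peptide catalog, version catalog-v1
# columns: peptide	provenance	citation
peptide	provenance	citation
VD	biopep	BIOPEP-UWM umami entry
VE	biopep	BIOPEP-UWM umami entry
VG	biopep	BIOPEP-UWM umami entry
DA	biopep	BIOPEP-UWM umami entry
VT	literature	peer-reviewed umami dipeptide report
SE	literature	peer-reviewed umami dipeptide report
IPP	literature	peer-reviewed umami tripeptide report
SD	literature	peer-reviewed umami dipeptide report
PN	literature	peer-reviewed umami dipeptide report
PSG	literature	peer-reviewed umami tripeptide report
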