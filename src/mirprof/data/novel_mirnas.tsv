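name	sequence	length_nt	read_count	strand	mfei
mko-miRN1-3p	UUAGGGUUUCAGUGAUCGAAAAC	23	14	-	0.85
mko-miRN2-3p	GUGAGCCAAGCAAGUAGUGUCGC	23	5	+	0.70
mko-miRN3-3p	UUGUCUCACUGCCUGUUGCACU	22	7	+	0.92
mko-miRN4-5p	UGCAGGUGAGAUGAUACCGUCA	22	15	-	0.72
mko-miRN5-3p	ACCGUGUUUCUCUGCCCAAUCAG	23	8	-	0.98
mko-miRN6-5p	CUGGGGAGUUGCACCCGGAGUA	22	6	-	0.79
mko-miRN7-3p	UUGUUUUGGGUGAAACGGGUGUU	23	93	+	0.97
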