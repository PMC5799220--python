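onset_s	duration_s	condition
0.0	6.0	WR
30.0	6.0	PV
60.0	6.0	FT
90.0	6.0	WR
120.0	6.0	PV
150.0	6.0	FT
180.0	6.0	WR
210.0	6.0	PV
240.0	6.0	FT
270.0	6.0	WR
300.0	6.0	PV
330.0	6.0	FT
360.0	6.0	WR
390.0	6.0	PV
420.0	6.0	FT
450.0	6.0	WR
480.0	6.0	PV
510.0	6.0	FT
540.0	6.0	WR
570.0	6.0	PV
600.0	6.0	FT
630.0	6.0	WR
660.0	6.0	PV
690.0	6.0	FT
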