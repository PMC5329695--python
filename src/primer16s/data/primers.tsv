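name	sequence	orientation	footprint_start	footprint_end
Bac1f	AAATTGAAGAGTTTGATC	forward	1	18
Bac8f(A)	AGAGTTTGATCATGGCTCAG	forward	8	27
Bac8f(C)	AGAGTTTGATCCTGGCTCAG	forward	8	27
UN1542r	TAAGGAGGTGATCCA	reverse	1528	1542
UN1541r(U)	AAGGAGGTGATCCAACC	reverse	1525	1541
UN1541r(C)	AAGGAGGTGATCCAGCC	reverse	1525	1541
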