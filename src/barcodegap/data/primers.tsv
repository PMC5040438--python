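name	sequence	source	used_at
LCO1490	GGTCAACAAATCATAAAGATATTGG	Folmer et al. 1994	SMNS;CCDB for ZSM;ZFMK
HCO2198	TAAACTTCAGGGTGACCAAAAAATCA	Folmer et al. 1994	SMNS;CCDB for ZSM;ZFMK
LepF1	ATTCAACCAATCATAAAGATATTGG	Hebert et al. 2004	CCDB for ZSM
LepR1	TAAACTTCTGGATGTCCAAAAAATCA	Hebert et al. 2004	CCDB for ZSM
C_LepFolF	cocktail:LepF1+LCO1490	BOLD public primer database	CCDB for ZSM
C_LepFolR	cocktail:LepR1+HCO2198	BOLD public primer database	CCDB for ZSM
LCO1490-JJ	CHACWAAYCATAAAGATATYGG	Astrin & Stueben 2008	ZFMK
HCO2198-JJ	AWACTTCVGGRTGVCCAAARAATCA	Astrin & Stueben 2008	ZFMK
LCO1490-JJ2	CHACWAAYCAYAARGAYATYGG	new	ZFMK
HCO2198-JJ2	ANACTTCNGGRTGNCCAAARAATCA	new	ZFMK
LCO1490-JJ4a	CNACNAAYCAYARRGAYATYGG	new	ZFMK
HCO2198-JJ4a	AIACYTCNGGRTGICCAAARAATC	new	ZFMK
LCO1490-JJ4	CIACIAAYCAYAARGAYATYGG	new	ZFMK
HCO2198-JJ4	ANACTTCNGGRTGNCCAAARAATC	new	ZFMK
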