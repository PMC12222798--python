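pathway_id	ligand	receptor
EGF_EGFR	EGF	EGFR
TGFA_EGFR	TGFA	EGFR
AREG_EGFR	AREG	EGFR
HBEGF_EGFR	HBEGF	EGFR
HBEGF_ERBB4	HBEGF	ERBB4
EGF_ERBB2	EGF	ERBB2
NRG1_ERBB2	NRG1	ERBB2
NRG1_ERBB3	NRG1	ERBB3
NRG1_ERBB4	NRG1	ERBB4
NRG2_ERBB3	NRG2	ERBB3
NRG2_ERBB4	NRG2	ERBB4
NRG3_ERBB4	NRG3	ERBB4
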