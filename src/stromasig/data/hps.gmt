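HPS	7-gene stromal-subtype prognostic signature	FGL2	PSME1	SP110	WARS	CCND2	CCND3	PNPT1
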