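class_name	pattern
ABRE	ACGTG
ABRE	YACGTGGC
DRE	RCCGAC
HSE	NGAANNTTCN
HSE	AGAANNTTCT
LTRE	CCGAAA
TC-rich	ATTTTCTTCA
TC-rich	GTTTTCTTAC
W-box	TTGACY
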