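motif_id	width	consensus
1	113	FPPSSSRETSAFANTRIDWKETPEAHVFKVDVPGLKKEEVKVEVEEDRVLQISGERSREKEEKNDKWHRVERSSGKFMRRFRLPENAKMDQIKASMENGVLTVTVPKEEEKKP
2	20	DVDKIKAKMENGVLTVTVPK
3	19	ADLPGLKKEDVKVQVEDNG
4	15	SNIFDPFSLDVFDPF
5	11	MSLIPRFFGGR
6	45	TDDATIGTASVLAAKLKMPRKVMNMTLVALLVLGIGLVVSNKMKS
7	15	RSYGKFSTSFNLPEN
8	21	VYEDFVPSTELVQEEDSDTLL
9	8	VKSIDISG
10	41	PSHEFYLETPRSLIAPSLSFPHVPQYMAQIEYKETPEAHIF
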