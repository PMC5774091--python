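>acd_seed_01 synthetic ACD-domain seed sequence
FYPSHSREQSAFAHTRIDWKETPWPHVHKVDVPGLKKWEVKVERTEDRVLQISGERSREKEEKNDKWPRVERSSEKFMRRFLLPENAKMDQIKPQNENGVLTVTVPKEEEHKP
>acd_seed_02 synthetic ACD-domain seed sequence
PPPSSSRETSAFWNTRIDWKQYPEPHVNKVEHPGLKKEEVKVPVEEDRVLMISGERSTNKEEKNDKWHRVERSSGKFMRRNRLPENAKMDQWDASMENGVLTVTSPKEEEKRP
>acd_seed_03 synthetic ACD-domain seed sequence
GPRSSSRETSAFANTRIDPKHTPEAIVPKVIVPGLKKEEGKVEVEQDRVLQISGERSREKKEKNDKWHRVERSSGKKMRRDRLPENAKMDQIKASMPNGVTTVTVPKEEEKWF
>acd_seed_04 synthetic ACD-domain seed sequence
FPPSSSGELSAFANTRIDWKETPEAHVFKVDVPGCKKEEVKTQVEEDRVLQISGTRWREKEEKNIKWHSVERSFIKFMRRFRLPNHAKMDQIKLSMENGVLTVTVPEEEEKKD
>acd_seed_05 synthetic ACD-domain seed sequence
FPWSSNRETSAFANIRIDWKETPEAHVFKCDKPALKKREVKVEVEEDRVLQISGERSREKEEKNDKWHRSECSSGKFMRRFNLPENAKGDQIKASMENGVLQVTSPKEEEMKH
>acd_seed_06 synthetic ACD-domain seed sequence
FPPSSSRETSAGANTRIDWEGTCEAHVFKVVVPGLKKCECKVEVTEDRVLDISGDRSREKEEKNDKWHRWERWSGKFMRRFRLAENAKMDQIKASMENLVITVTVPKEEEKFP
>acd_seed_07 synthetic ACD-domain seed sequence
FPPLSSRETSLFANTRIAWNEIPEAHVFKVDVPPVKAEEVKVEVEEDRVLQISGERSREKEEKNQKWHRVERSSGKHMRRFRRPENAKMDQAKASKENGVLGVEVPKEEEAKT
>acd_seed_08 synthetic ACD-domain seed sequence
KPPGSSRETSAFANTSYDWKETPEWHVFKVDVPGLKKEEVKVEVERDRVLQISGERSREVEEALDIWHRVERSSGKFTRRFECPDNAKMDQIKASMENGVLTVSVPKEEEKKP
>acd_seed_09 synthetic ACD-domain seed sequence
FPPSSSREALRFANTRHDWKETPEAHVFTVDVPGLKFEEVKVEVEEDRVLQISGMRSREKEIKNYKVHRVERSSGGCMRRFRLPENAKMDQIKAPMENAVLTVWQPKEEEKKP
>acd_seed_10 synthetic ACD-domain seed sequence
FPVSSSRGTSAFRNWRIRWKETPEAHVFKVDVPSLVKEEVKSWVEEDRVQQIWGERSREKEQKNDKWHRVERSSLKFMRKFRLWENAKMDQIKASMENGVLTVTVPKEEEKKP
>acd_seed_11 synthetic ACD-domain seed sequence
WPPVSSRECSATANTRIDWPYTPEAQLFTVDVPPFKKEEVKVEVEEDVDLQISGERSREKEEKNDKAMRVERSSGKFMRRFRLPENRKMDQIKASMENGFLTVTVPKEEEKKP
>acd_seed_12 synthetic ACD-domain seed sequence
NPPSSSNQESAFGNDRIPWKETPEAHDVKVDVPGIKKEEVKVEVEEDRVHHISGERSREKEEENDLWHRVERSSGKFMRRFRLPENAKMDQIKASMENGVLTVTVQKEEYKVP
>acd_seed_13 synthetic ACD-domain seed sequence
FPPSGSREFSAFANTRIDNKETPEAHAFSLDVPGLKKEEVKVMVEEDRVLQISQMWIREKEEKNDKWHRWERSSGKFMRRFRLPENAKMDQIKMSMENGVLTVTVPSCEEWKP
>acd_seed_14 synthetic ACD-domain seed sequence
FPPSSSRETSAFQNTRIDMKEWPEAHVFKVDVKGLKKEECKVEVEEDRPLQISGERSREKERHMDKWHRVERSSSIFMRRFRLPENAKMDQIKASVENGFLTDTVPKEWEKQP
>acd_seed_15 synthetic ACD-domain seed sequence
FKPSSSRETSQFANTRIDWKEYQEAHVFKVDVPGLHKMCVFVEVEEDRVLQISGERIRFKEEKNDKWHRVERSSGKHMRRFRLPETAKMDQIKAMMKNYVLTVTVPKEEEKKP
>acd_seed_16 synthetic ACD-domain seed sequence
FPPDSSRETSAFANTRIDWKYTPEAHVFKVDCPGLKKEDHKVEVEEDRSEQISGERSREKEEKRDKWHEVERSSGKRARRFRLEENAKMDQIYASMENGVLTVPVPKEEEYKG
>acd_seed_17 synthetic ACD-domain seed sequence
FPPSSSRHTSAPANERIDWKTTAEAHVFKVAVPGLLKEEVKVEVEEDRVVQISGELQQEKQEKGDKWHRVERSSGKFMRLFAFPENAKMDQIKASMENGVLTVTVPTEEEKKP
>acd_seed_18 synthetic ACD-domain seed sequence
FPPSSSRETSAFPNTRIDWPETPPAHVFKVIVIGNLKEKNAVEVHEFRVLQISGERSREKEEKNDKWHRVERSSGKFMRRFRLPENAKMDQIKASMENGVLTVRVHKWEEYKP
>acd_seed_19 synthetic ACD-domain seed sequence
APPSSSRETSAFANWRIDWKNTPQAFVFKVNSRGLKKEEVKVEVEEDRPLQISQERSREHEERNDKWHRVDRSSYKFMRRFRLPENAKMDQIKATGENGVATVTVPKEEEKKP
>acd_seed_20 synthetic ACD-domain seed sequence
FPPSSSRETSYFANTRADWKETNEAHVFKVDVPKVKKIEVKVEVEEDRVMQISGERSREKEEKNDKWHRVERSSGKFQKRFRLGCNTKMDQILAKMENGVLTVTVPNSEEKKP
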