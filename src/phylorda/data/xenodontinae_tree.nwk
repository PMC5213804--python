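((Philodryas_aestiva,Philodryas_olfersii,Philodryas_patagoniensis)Philodryadini,(Thamnodynastes_chaquensis,Thamnodynastes_hypoconia,Thamnodynastes_strigatus)Tachimenini,(Helicops_infrataeniatus,Helicops_leopardinus)Hydropsini,((Hydrodynastes_gigas)Hydrodynastini,(Paraphimophis_rustica,Boiruna_maculata)Pseudoboini)Hydrodynastini_Pseudoboini,((Erythrolamprus_jaegeri,Erythrolamprus_poecilogyrus,Erythrolamprus_semiaureus)Erythrolamprus,Lygophis_anomalus,(Xenodon_dorbingyi,Xenodon_merremii)Xenodon)Xenodontini);
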