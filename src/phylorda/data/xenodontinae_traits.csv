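species,tribe,N,RM,RF,RP,MF,SU,HU
Philodryas_aestiva,Philodryadini,21,O,0.8,M,10,T,S
Philodryas_olfersii,Philodryadini,22,O,0.5,L,7,A,Fo
Philodryas_patagoniensis,Philodryadini,118,O,0.9,H,12,T,S
Thamnodynastes_chaquensis,Tachimenini,48,V,0.8,M,11,T,W
Thamnodynastes_hypoconia,Tachimenini,67,V,0.5,L,8,AQ,W
Thamnodynastes_strigatus,Tachimenini,20,V,0.5,M,11,AQ,W
Helicops_infrataeniatus,Hydropsini,65,V,0.5,M,17,AQ,W
Helicops_leopardinus,Hydropsini,95,V,0.5,M,15,AQ,W
Hydrodynastes_gigas,Hydrodynastini,77,O,0.7,H,23,AQ,W
Paraphimophis_rustica,Pseudoboini,20,O,0.6,M,9,T,S
Boiruna_maculata,Pseudoboini,18,O,0.5,L,8,T,S
Erythrolamprus_jaegeri,Xenodontini,21,O,0.6,L,6,T,G
Erythrolamprus_poecilogyrus,Xenodontini,93,O,0.6,M,8,T,G
Erythrolamprus_semiaureus,Xenodontini,90,O,0.9,H,14,AQ,W
Lygophis_anomalus,Xenodontini,62,O,0.5,L,7,T,S
Xenodon_dorbingyi,Xenodontini,32,O,0.7,M,11,F,S
Xenodon_merremii,Xenodontini,49,O,0.8,H,16,T,G
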