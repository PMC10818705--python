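# Cu(II/I) and Tyr109(./0) peak potentials, DPV, V vs NHE; estimated error +/- 10 mV
ph,species,potential_v_nhe
5,Cu,0.348
6,Cu,0.339
7,Cu,0.312
8,Cu,0.292
9,Cu,0.288
5,Tyr109Met122,1.04
6,Tyr109Met122,0.975
7,Tyr109Met122,0.930
8,Tyr109Met122,0.877
9,Tyr109Met122,0.876
5,Tyr109Gln122,1.02
6,Tyr109Gln122,0.962
7,Tyr109Gln122,0.927
8,Tyr109Gln122,0.898
9,Tyr109Gln122,0.893
5,Tyr109Arg122,1.02
6,Tyr109Arg122,0.980
7,Tyr109Arg122,0.912
8,Tyr109Arg122,0.880
9,Tyr109Arg122,0.876
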