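# Observed rate constants for Cu(I) oxidation by flash-quench generated Ru(III), s^-1
ph,variant,k_obs_s,k_err_s
6,Met122,6.8e3,0.5e3
6,Gln122,6.3e3,0.6e3
6,Arg122,5.4e3,1.1e3
6,Lys122,5.7e3,0.3e3
7,Met122,1.2e4,0.1e4
7,Gln122,1.1e4,0.1e4
7,Arg122,1.1e4,0.1e4
7,Lys122,1.2e4,0.2e4
8,Met122,1.8e4,0.1e4
8,Gln122,1.6e4,0.1e4
8,Arg122,1.6e4,0.1e4
8,Lys122,1.7e4,0.2e4
9,Met122,2.6e4,0.1e4
9,Gln122,2.1e4,0.1e4
9,Arg122,2.2e4,0.1e4
9,Lys122,1.8e4,0.2e4
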