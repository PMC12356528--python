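id	role	structure	stereo	racemic	probe	notes
mesyl	cap	C[SH:1](=O)=O	none	false		methanesulfonyl; attaches through S
acetyl	cap	C[CH:1]=O	none	false		acetyl; attaches through the carbonyl C
methyl	cap	[CH4:1]	none	false		methyl
phenyl	cap	[cH:1]1ccccc1	none	false		phenyl (N-arylation)
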