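id	role	structure	stereo	racemic	probe	notes
pyrimidin-5-yl	fragment	[cH:1]1cncnc1	none	false		aryl from 5-bromopyrimidine, the exemplar 2-D fragment hit
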