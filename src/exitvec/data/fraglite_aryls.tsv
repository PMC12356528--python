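id	role	structure	stereo	racemic	probe	notes
pyrimidin-5-yl	fragment	[cH:1]1cncnc1	none	false		from 5-bromopyrimidine
4-methoxyphenyl	fragment	[cH:1]1ccc(OC)cc1	none	false		from 4-bromoanisole
2-methoxyphenyl	fragment	[cH:1]1ccccc1OC	none	false		from 2-bromoanisole
pyridin-3-yl	fragment	[cH:1]1cccnc1	none	false		pyridine
pyridin-4-yl	fragment	[cH:1]1ccncc1	none	false		pyridine
quinolin-6-yl	fragment	[cH:1]1ccc2ncccc2c1	none	false		quinoline (representative attachment position)
indol-5-yl	fragment	[cH:1]1ccc2[nH]ccc2c1	none	false		indole (representative attachment position)
1H-indazol-5-yl	fragment	[cH:1]1ccc2[nH]ncc2c1	none	false		indazole (representative attachment position)
benzofuran-5-yl	fragment	[cH:1]1ccc2occc2c1	none	false		benzofuran (representative attachment position)
thiophen-3-yl	fragment	[cH:1]1ccsc1	none	false		thiophene
1H-pyrazol-4-yl	fragment	[cH:1]1c[nH]nc1	none	false		pyrazole
benzimidazol-5-yl	fragment	[cH:1]1ccc2[nH]cnc2c1	none	false		benzimidazole (representative attachment position)
furan-3-yl	fragment	[cH:1]1ccoc1	none	false		furan
quinazolin-6-yl	fragment	[cH:1]1ccc2ncncc2c1	none	false		quinazoline (representative attachment position)
7-azaindol-5-yl	fragment	[cH:1]1cc2cc[nH]c2nc1	none	false		7-azaindole (representative attachment position)
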