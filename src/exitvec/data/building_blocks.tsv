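id	role	structure	stereo	racemic	probe	notes
1a	building_block	C1C[NH:2][C@@H:1]2C[C@@H]12	cis	true	C[C@:1]12C[C@H]1CC[NH:2]2	fused pyrrolidine-2,3-cyclopropane (2-azabicyclo[3.1.0]hexane); handle on the ring-junction carbon bonded to N
1b	building_block	C1C[NH:2]CCC12C[CH2:1]2	none	true	C[C@@H:1]1CC12CC[NH:2]CC2	spiro piperidine-4-cyclopropane (6-azaspiro[2.5]octane); handle on a cyclopropane methylene
1c	building_block	C1C2(C[NH:2]C2)[CH2:1]1	none	true	C[C@@H:1]1CC12C[NH:2]C2	spiro azetidine-3-cyclopropane (5-azaspiro[2.3]hexane); handle on a cyclopropane methylene
1d	building_block	C1C[NH:2]C[C@]12C[CH2:1]2	syn	true	C[C@@H:1]1C[C@@]12CC[NH:2]C2	spiro pyrrolidine-3-cyclopropane (5-azaspiro[2.4]heptane), handle syn to the N-proximal arm; diastereomer of 1e (pair assignment flagged: resolved crystallographically in the original work)
1e	building_block	C1C[NH:2]C[C@@]12C[CH2:1]2	anti	true	C[C@@H:1]1C[C@]12CC[NH:2]C2	spiro pyrrolidine-3-cyclopropane (5-azaspiro[2.4]heptane), handle anti to the N-proximal arm; diastereomer of 1d (pair assignment flagged)
1f	building_block	C1C[C@H]2C[C@]3(C[C@@H]1[NH:2]2)C[CH2:1]3	anti	false	C[C@@H:1]1C[C@]12C[C@H]1CC[C@@H](C2)[NH:2]1	spiro cyclopropane on nortropane C3 (spiro[cyclopropane-1,3'-8-azabicyclo[3.2.1]octane]); handle anti to the two-carbon bridge; single diastereomer
1g	building_block	C1C[NH:2]C[C@H]2[C@@H]1[CH2:1]2	exo	true	C[C@H:1]1[C@@H]2CC[NH:2]C[C@@H]21	fused piperidine-3,4-cyclopropane; handle on the cyclopropane apex, convex (exo) face
1h	building_block	C1[C@@H]2[C@H](C[NH:2]1)[CH2:1]2	exo	false	C[C@H:1]1[C@@H]2C[NH:2]C[C@@H]21	fused pyrrolidine-3,4-cyclopropane (3-azabicyclo[3.1.0]hexane); handle on the apex, exo; meso
1i	building_block	C1C[C@@H]2[C@@H]([CH2:1]2)[NH:2]C1	exo	true	C[C@H:1]1[C@@H]2CCC[NH:2][C@@H]21	fused piperidine-2,3-cyclopropane (2-azabicyclo[4.1.0]heptane); handle on the apex, exo
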