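lineage_id	zoonotic_candidate	best_match_label	detected_in_richness
Bartonella_schoenbuchensis_1	true	Bartonella schoenbuchensis	2
Streptococcus_sp_1	true	Streptococcus sp.	2;3
Capnocytophaga_canimorsus_1	true	Capnocytophaga canimorsus	1;2;3
Capnocytophaga_canimorsus_2	true	Capnocytophaga canimorsus	3
Capnocytophaga_canimorsus_3	true	Capnocytophaga canimorsus	3
Capnocytophaga_canimorsus_4	true	Capnocytophaga canimorsus	3
Capnocytophaga_sp_S12-14	true	Capnocytophaga sp. S12-14	2
Corynebacterium_urealyticum_1	true	Corynebacterium urealyticum	3
Corynebacterium_urealyticum_2	true	Corynebacterium urealyticum	3
Finegoldia_magna_1	true	Finegoldia magna	3
Helicobacter_sp_hokurin-1	true	Helicobacter sp. hokurin-1	3
Neisseria_mucosa_1	true	Neisseria mucosa	3
Leptotrichia_sp_uncultured_1	true	Uncultured Leptotrichia sp.	3
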