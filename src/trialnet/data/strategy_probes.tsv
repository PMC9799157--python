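strategy	mean_rating	sd_rating	interexperiment_r
Significance	3.18	1.60	0.92
Pers_Feelings	3.62	1.59	0.93
Emotions	3.01	1.62	0.91
Pers_Past_Exper	4.15	1.71	0.93
Sequence_Events	3.61	1.86	0.91
Loc_Obj_Places	3.70	1.98	0.89
Loc_People	2.83	1.82	0.86
Others_Feelings	2.90	1.75	0.92
Moral_Principles	1.89	1.25	0.91
Relationships	2.16	1.30	0.96
Others_Personality	2.27	1.58	0.88
Visual_Imagery	4.29	1.89	0.81
Recent_Thoughts	2.49	1.53	0.91
Difficulty	3.02	1.65	0.93
Facts	3.85	1.95	0.86
Specificity	4.21	1.91	0.66
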