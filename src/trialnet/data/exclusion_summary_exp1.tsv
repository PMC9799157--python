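cohort	n_enrolled	exc_time	exc_clicks	exc_checks	exc_patterned	exc_age	exc_other	n_included	mean_age	n_female
1	25	4	1	0	2	0	0	18	23.0	7
2	25	4	0	1	3	0	0	17	22.8	6
3	25	2	0	0	5	0	0	18	22.2	10
4	25	0	0	0	3	0	0	22	22.7	14
5	25	1	0	1	2	0	0	21	23.0	11
6	25	0	1	0	2	1	0	21	22.6	12
7	25	2	0	0	4	0	0	19	22.5	7
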