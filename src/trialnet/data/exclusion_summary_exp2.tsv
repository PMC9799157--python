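cohort	n_enrolled	exc_time	exc_clicks	exc_checks	exc_patterned	exc_age	exc_other	n_included	mean_age	n_female
1	50	3	1	1	8	0	0	37	22.9	21
2	50	5	0	0	6	0	0	39	22.3	26
3	50	5	0	1	3	1	0	40	22.4	18
4	50	4	0	1	3	0	0	42	22.5	25
5	50	2	1	0	6	0	1	40	22.6	27
6	50	3	0	1	4	2	0	40	22.3	29
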