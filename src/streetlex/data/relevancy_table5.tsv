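term	cosine	annotator1_hits	annotator2_hits	sample_size	on_candidate_list
edibles	0.58	180	185	200	1
weed	0.71	186	177	200	1
ganja	1.00	190	169	200	1
kush	0.77	192	165	200	1
sativa	0.68	176	177	200	1
sour_diesel	0.68	91	98	112	1
indica	0.54	132	170	200	1
devil's_lettuce	0.67	145	150	200	1
dro	0.72	136	134	200	1
dabs	0.54	123	142	200	1
purp	0.67	75	59	200	1
pot	0.49	64	69	200	1
dank	0.54	56	43	200	1
herb	0.48	37	54	200	1
reggie	0.47	41	46	200	1
wax	0.45	42	43	200	0
nug	0.36	16	55	200	0
mary_jane	0.31	24	36	200	0
pineapple_express	0.38	29	27	200	0
chronic	0.26	35	18	200	0
shatter	0.16	18	32	200	0
bud	0.36	20	21	200	0
skunk	0.31	24	14	200	0
haze	0.36	13	17	200	0
exotics	0.19	9	12	143	0
hydro	0.32	15	12	200	0
shard	0.14	5	4	138	0
flower	0.29	1	9	200	0
fire	0.30	0	10	200	0
mud	0.31	1	4	200	0
flame	0.40	0	5	200	0
green	0.25	1	3	200	0
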