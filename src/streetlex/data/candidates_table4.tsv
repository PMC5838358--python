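rank	term	cosine
1	kush	0.772
2	reefer	0.738
3	dro	0.722
4	reefa	0.717
5	weed	0.712
6	sativa	0.682
7	sour_diesel	0.676
8	purp	0.670
9	devils_lettuce	0.670
10	og_kush	0.667
11	doja	0.654
12	kief	0.649
13	gorilla_glue	0.640
14	thrax	0.633
15	piff	0.632
16	weeed	0.605
17	moonrocks	0.603
18	pacc	0.603
19	tookah	0.601
20	devil's_lettuce	0.600
21	moonrock	0.598
22	tooka	0.587
23	edibles	0.584
24	mids	0.581
25	bubba_kush	0.563
26	gasss	0.562
27	gass	0.562
28	marijuana	0.556
29	ganj	0.550
30	dodi	0.546
31	indica	0.544
32	jazz_cabbage	0.543
33	faygo	0.540
34	dank	0.539
35	dabs	0.538
36	oregano	0.533
37	wata	0.527
38	bammer	0.527
39	tincture	0.517
40	marijuanas	0.514
41	k2	0.513
42	thc	0.497
43	gas	0.495
44	rosin	0.493
45	smarties	0.492
46	pot	0.490
47	🍃_🍃	0.489
48	gassss	0.488
49	danky	0.487
50	hemp	0.483
51	weeeeed	0.480
52	herb	0.477
53	kool_aid	0.473
54	hawaiian_punch	0.472
55	cannabis	0.469
56	reggie	0.469
57	jolly_ranchers	0.468
58	kushy	0.465
59	grape_juice	0.464
60	cheech	0.461
61	goop	0.461
62	khalifa_kush	0.461
63	tropical_fusion	0.461
64	broccoli	0.460
65	medicinal	0.460
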