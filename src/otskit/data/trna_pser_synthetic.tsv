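# SYNTHETIC stand-in for the pSer suppressor tRNA (UAG-reading, CUA
# anticodon).  The documented identity positions are faithful: G1:C72 and
# C2:G71 acceptor-stem pairs, discriminator U73, anticodon CUA (34-36), short
# variable loop (positions 44-48 only, no extended loop).  All other bases are
# plausible filler, NOT the published sequence.
sprinzl_position	base
1	G
2	C
3	G
4	G
5	C
6	G
7	G
8	U
9	A
10	G
11	C
12	U
13	C
14	A
15	G
16	U
17	U
18	G
19	G
20	U
21	A
22	G
23	A
24	G
25	C
26	G
27	C
28	C
29	A
30	G
31	G
32	C
33	U
34	C
35	U
36	A
37	A
38	A
39	C
40	C
41	U
42	G
43	G
44	A
45	G
46	G
47	U
48	C
49	G
50	G
51	G
52	G
53	G
54	U
55	U
56	C
57	G
58	A
59	A
60	U
61	C
62	C
63	C
64	C
65	C
66	C
67	C
68	G
69	C
70	C
71	G
72	C
73	U
74	C
75	C
76	A
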