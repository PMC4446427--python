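d	minor_groove_inward	isat_sign
-73	1	-1
-72	1	-1
-71	1	-1
-70	0	1
-69	0	1
-68	0	1
-67	0	1
-66	0	1
-65	1	-1
-64	1	-1
-63	1	-1
-62	1	-1
-61	1	-1
-60	0	1
-59	0	1
-58	0	1
-57	0	1
-56	0	1
-55	1	-1
-54	1	-1
-53	1	-1
-52	1	-1
-51	1	-1
-50	1	-1
-49	0	1
-48	0	1
-47	0	1
-46	0	1
-45	0	1
-44	1	-1
-43	1	-1
-42	1	-1
-41	1	-1
-40	1	-1
-39	0	1
-38	0	1
-37	0	1
-36	0	1
-35	0	1
-34	1	-1
-33	1	-1
-32	1	-1
-31	1	-1
-30	1	-1
-29	1	-1
-28	0	1
-27	0	1
-26	0	1
-25	0	1
-24	0	1
-23	1	-1
-22	1	-1
-21	1	-1
-20	1	-1
-19	1	-1
-18	0	1
-17	0	1
-16	0	1
-15	0	1
-14	0	1
-13	1	-1
-12	1	-1
-11	1	-1
-10	1	-1
-9	1	-1
-8	1	-1
-7	0	1
-6	0	1
-5	0	1
-4	0	1
-3	0	1
-2	1	-1
-1	1	-1
0	1	-1
1	1	-1
2	1	-1
3	0	1
4	0	1
5	0	1
6	0	1
7	0	1
8	1	-1
9	1	-1
10	1	-1
11	1	-1
12	1	-1
13	1	-1
14	0	1
15	0	1
16	0	1
17	0	1
18	0	1
19	1	-1
20	1	-1
21	1	-1
22	1	-1
23	1	-1
24	0	1
25	0	1
26	0	1
27	0	1
28	0	1
29	1	-1
30	1	-1
31	1	-1
32	1	-1
33	1	-1
34	1	-1
35	0	1
36	0	1
37	0	1
38	0	1
39	0	1
40	1	-1
41	1	-1
42	1	-1
43	1	-1
44	1	-1
45	0	1
46	0	1
47	0	1
48	0	1
49	0	1
50	1	-1
51	1	-1
52	1	-1
53	1	-1
54	1	-1
55	1	-1
56	0	1
57	0	1
58	0	1
59	0	1
60	0	1
61	1	-1
62	1	-1
63	1	-1
64	1	-1
65	1	-1
66	0	1
67	0	1
68	0	1
69	0	1
70	0	1
71	1	-1
72	1	-1
73	1	-1
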