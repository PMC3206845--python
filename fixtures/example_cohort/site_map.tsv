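index	sense_c_pos	antisense_c_pos
1	19	20
2	39	40
3	53	54
4	68	69
5	88	89
6	110	111
7	126	127
8	142	143
9	162	163
10	177	178
11	193	194
12	209	210
13	226	227
14	248	249
15	263	264
16	283	284
17	304	305
18	324	325
19	342	343
20	359	360
21	396	397
22	413	414
23	427	428
24	442	443
25	460	461
26	482	483
27	500	501
28	516	517
29	535	536
30	554	555
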