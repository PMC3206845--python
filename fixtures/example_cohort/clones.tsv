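sample_id	strand	clone_id	site_1	site_2	site_3	site_4	site_5	site_6	site_7	site_8	site_9	site_10	site_11	site_12	site_13	site_14	site_15	site_16	site_17	site_18	site_19	site_20
T1	antisense	T1_cl1	1	1	1	1	1	1	1	1	1	1	1	0	0	1	0	1	0	0	0	1
T1	antisense	T1_cl2	1	0	1	1	1	0	1	0	1	1	1	1	1	1	1	1	0	1	1	1
T1	antisense	T1_cl3	0	1	0	0	1	1	1	0	0	1	1	1	1	1	1	1	1	1	1	0
T1	antisense	T1_cl4	0	1	0	1	1	1	1	0	0	1	1	0	1	1	1	1	1	1	1	1
T1	antisense	T1_cl5	0	1	0	1	1	1	1	1	0	0	1	0	0	1	0	1	1	0	0	1
T1	antisense	T1_cl6	1	0	0	1	1	1	1	0	1	1	1	0	1	0	0	0	0	1	1	1
T1	antisense	T1_cl7	1	1	1	0	0	1	0	0	1	0	1	1	1	1	1	1	1	0	0	1
T1	antisense	T1_cl8	1	1	1	1	1	1	1	0	1	1	0	0	0	1	1	1	1	0	0	0
T1	antisense	T1_cl9	1	0	0	1	1	0	0	1	0	0	1	1	1	1	1	1	0	1	0	1
T1	antisense	T1_cl10	1	1	1	1	0	1	1	0	1	1	1	1	1	1	1	1	1	1	0	1
T1	antisense	T1_cl11	0	1	0	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1
T1	antisense	T1_cl12	1	1	1	1	1	0	1	1	1	1	1	1	1	0	1	1	1	0	1	0
T1	antisense	T1_cl13	1	0	1	0	1	1	1	1	1	0	1	1	1	1	0	1	1	0	1	1
T1	antisense	T1_cl14	1	1	0	1	1	1	1	1	1	0	0	1	1	1	0	0	0	1	1	0
T1	antisense	T1_cl15	1	1	1	0	0	1	0	1	1	1	0	1	0	0	0	1	1	1	1	1
T1	antisense	T1_cl16	1	1	1	0	0	0	0	0	1	0	1	1	1	0	1	0	1	1	0	0
T1	antisense	T1_cl17	1	1	1	1	1	1	0	1	0	1	0	1	1	0	1	0	0	0	1	1
T2	antisense	T2_cl1	1	1	0	0	0	0	1	1	0	0	1	0	0	0	1	1	0	0	0	1
T2	antisense	T2_cl2	0	1	0	1	1	1	0	1	0	0	1	0	1	0	0	1	1	1	0	0
T2	antisense	T2_cl3	1	0	0	0	0	1	1	0	1	0	0	0	1	0	1	0	1	1	0	0
T2	antisense	T2_cl4	1	1	1	1	0	0	1	0	0	0	0	0	0	0	1	0	1	0	0	1
T2	antisense	T2_cl5	0	0	1	0	1	0	0	1	1	0	0	1	1	0	0	1	0	0	0	1
T2	antisense	T2_cl6	1	0	0	1	0	0	1	1	0	1	0	0	1	0	0	1	0	0	1	1
T2	antisense	T2_cl7	1	0	0	0	0	1	0	0	1	0	1	1	1	0	0	0	1	1	1	0
T2	antisense	T2_cl8	1	0	0	0	0	0	0	1	1	1	1	0	1	0	0	0	1	0	0	1
T2	antisense	T2_cl9	1	0	0	1	0	0	0	1	0	0	1	1	0	0	0	0	0	1	0	0
T2	antisense	T2_cl10	1	1	1	0	1	1	0	0	0	0	0	1	0	1	1	0	1	0	1	1
T2	antisense	T2_cl11	1	0	0	1	0	1	0	0	1	1	1	1	0	0	1	0	0	1	1	1
A1	antisense	A1_cl1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl4	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl5	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl6	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl7	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl8	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl9	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl10	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl11	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl12	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl13	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl14	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl15	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A1	antisense	A1_cl16	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl4	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0
A2	antisense	A2_cl5	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl6	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl7	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl8	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl9	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl10	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl11	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl12	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl13	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl14	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl15	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl16	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl17	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A2	antisense	A2_cl18	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0
N1	antisense	N1_cl2	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl4	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl5	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl6	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl7	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl8	0	0	0	1	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0
N1	antisense	N1_cl9	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0
N1	antisense	N1_cl10	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0
N1	antisense	N1_cl11	0	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl12	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl13	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl14	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	1
N1	antisense	N1_cl15	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N1	antisense	N1_cl16	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0
N2	antisense	N2_cl1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl3	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0
N2	antisense	N2_cl4	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0
N2	antisense	N2_cl5	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl6	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl7	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl8	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl9	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl10	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl11	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl12	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl13	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1
N2	antisense	N2_cl14	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl15	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl16	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0
N2	antisense	N2_cl17	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
N2	antisense	N2_cl18	0	0	0	0	0	1	0	0	0	0	1	0	0	0	0	0	0	1	0	0
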