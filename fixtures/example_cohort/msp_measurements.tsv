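sample_id	assay	replicate	cq
T1	bs_actin	1	30.7669
T1	bs_actin	2	30.7338
T1	sense	1	
T1	sense	2	
T1	antisense	1	31.3272
T1	antisense	2	31.5087
T2	bs_actin	1	30.5521
T2	bs_actin	2	30.8132
T2	sense	1	31.9097
T2	sense	2	31.9263
T2	antisense	1	31.8553
T2	antisense	2	31.7788
T3	bs_actin	1	30.8073
T3	bs_actin	2	30.5556
T3	sense	1	31.9539
T3	sense	2	32.5797
T3	antisense	1	
T3	antisense	2	
T4	bs_actin	1	30.9416
T4	bs_actin	2	30.6095
T4	sense	1	31.4305
T4	sense	2	32.1306
T4	antisense	1	33.5409
T4	antisense	2	33.3965
T5	bs_actin	1	30.7745
T5	bs_actin	2	30.8612
T5	sense	1	32.5009
T5	sense	2	33.5281
T5	antisense	1	32.2505
T5	antisense	2	32.1464
A1	bs_actin	1	31.1577
A1	bs_actin	2	31.0797
A1	sense	1	
A1	sense	2	
A1	antisense	1	
A1	antisense	2	
A2	bs_actin	1	31.2087
A2	bs_actin	2	31.1728
A2	sense	1	34.9175
A2	sense	2	35.3595
A2	antisense	1	36.9859
A2	antisense	2	36.4627
A3	bs_actin	1	30.8387
A3	bs_actin	2	31.2335
A3	sense	1	
A3	sense	2	
A3	antisense	1	34.8231
A3	antisense	2	34.0715
A4	bs_actin	1	30.7392
A4	bs_actin	2	30.5854
A4	sense	1	
A4	sense	2	
A4	antisense	1	34.0613
A4	antisense	2	34.6455
A5	bs_actin	1	30.7735
A5	bs_actin	2	30.7361
A5	sense	1	
A5	sense	2	
A5	antisense	1	33.8635
A5	antisense	2	33.9726
C1	bs_actin	1	30.6811
C1	bs_actin	2	30.8139
C1	sense	1	
C1	sense	2	
C1	antisense	1	36.5622
C1	antisense	2	37.9731
C2	bs_actin	1	30.6834
C2	bs_actin	2	30.9845
C2	sense	1	
C2	sense	2	
C2	antisense	1	34.2321
C2	antisense	2	33.7552
C3	bs_actin	1	30.8448
C3	bs_actin	2	30.8683
C3	sense	1	
C3	sense	2	
C3	antisense	1	
C3	antisense	2	
C4	bs_actin	1	30.8816
C4	bs_actin	2	30.8333
C4	sense	1	32.8873
C4	sense	2	32.4439
C4	antisense	1	34.7088
C4	antisense	2	33.7687
H1	bs_actin	1	30.335
H1	bs_actin	2	30.443
H1	sense	1	
H1	sense	2	
H1	antisense	1	34.4153
H1	antisense	2	35.5293
H2	bs_actin	1	30.9995
H2	bs_actin	2	30.992
H2	sense	1	
H2	sense	2	
H2	antisense	1	34.1649
H2	antisense	2	34.3847
H3	bs_actin	1	30.9893
H3	bs_actin	2	30.8122
H3	sense	1	
H3	sense	2	
H3	antisense	1	34.5295
H3	antisense	2	34.1401
H4	bs_actin	1	30.6074
H4	bs_actin	2	30.9979
H4	sense	1	
H4	sense	2	
H4	antisense	1	
H4	antisense	2	
M1	bs_actin	1	30.7009
M1	bs_actin	2	31.051
M1	sense	1	
M1	sense	2	
M1	antisense	1	
M1	antisense	2	
X1	bs_actin	1	30.6262
X1	bs_actin	2	30.5907
X1	sense	1	
X1	sense	2	
X1	antisense	1	
X1	antisense	2	
X2	bs_actin	1	30.9866
X2	bs_actin	2	30.833
X2	sense	1	
X2	sense	2	
X2	antisense	1	
X2	antisense	2	
N1	bs_actin	1	31.1695
N1	bs_actin	2	30.6142
N1	sense	1	
N1	sense	2	
N1	antisense	1	38.0305
N1	antisense	2	35.2881
N2	bs_actin	1	31.0707
N2	bs_actin	2	31.2073
N2	sense	1	
N2	sense	2	
N2	antisense	1	35.472
N2	antisense	2	37.1023
N3	bs_actin	1	31.1052
N3	bs_actin	2	31.2949
N3	sense	1	
N3	sense	2	
N3	antisense	1	35.2437
N3	antisense	2	36.0448
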