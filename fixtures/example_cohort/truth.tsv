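sample_id	group	sense_fraction	antisense_fraction	sense_msp_truth	antisense_msp_truth	sense_bsp_truth	antisense_bsp_truth
T1	HCC	0.0	0.699787	0	1	0	1
T2	HCC	0.555981	0.421846	1	1	1	1
T3	HCC	0.344202	0.0	1	0	1	0
T4	HCC	0.537138	0.150629	1	1	1	1
T5	HCC	0.218311	0.267767	1	1	1	1
A1	adjacent_non_HCC	0.0	0.0	0	0	0	0
A2	adjacent_non_HCC	0.049292	0.025326	1	0	1	1
A3	adjacent_non_HCC	0.0	0.088869	0	1	0	1
A4	adjacent_non_HCC	0.0	0.082993	0	1	0	1
A5	adjacent_non_HCC	0.0	0.117593	0	1	0	1
C1	cirrhosis	0.0	0.015033	0	0	0	1
C2	cirrhosis	0.0	0.118448	0	1	0	1
C3	cirrhosis	0.0	0.0	0	0	0	0
C4	cirrhosis	0.273396	0.089718	1	1	1	1
H1	hepatitis	0.0	0.03275	0	0	0	1
H2	hepatitis	0.0	0.062993	0	1	0	1
H3	hepatitis	0.0	0.109651	0	1	0	1
H4	hepatitis	0.0	0.0	0	0	0	0
M1	mouse_liver	0.0	0.0	0	0	0	0
X1	nonliver	0.0	0.0	0	0	0	0
X2	nonliver	0.0	0.0	0	0	0	0
N1	normal_liver	0.0	0.036326	0	0	0	1
N2	normal_liver	0.0	0.015625	0	0	0	1
N3	normal_liver	0.0	0.066475	0	1	0	1
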