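sample_id	group	age	sex	hbv	hcv	stage	grade	afp_ng_ml	tumor_size_cm
T1	HCC	49.80	M	1	0	1	2	75.94	5.80
T2	HCC	62.40	F	0	0	2	2	2.40	9.30
T3	HCC	66.10	M	1	0	3	3	29.35	4.50
T4	HCC	73.90	M	1	0	1	3	20.61	4.00
T5	HCC	71.00	M	1	0	1	1	17.02	0.50
A1	adjacent_non_HCC	62.70	M	0	0			0.40	
A2	adjacent_non_HCC	53.30	F	0	0			13.73	
A3	adjacent_non_HCC	50.10	F	0	1			0.76	
A4	adjacent_non_HCC	51.60	M	0	1			0.72	
A5	adjacent_non_HCC	36.30	F	0	1			8.86	
C1	cirrhosis	43.90	F	0	0			0.69	
C2	cirrhosis	56.10	M	0	1			0.89	
C3	cirrhosis	57.10	M	1	0			17.63	
C4	cirrhosis	57.60	M	0	1			0.76	
H1	hepatitis	49.10	M	0	1			21.69	
H2	hepatitis	65.50	F	0	0			1.44	
H3	hepatitis	61.20	F	0	1			7.45	
H4	hepatitis	45.30	M	1	0			1.27	
M1	mouse_liver	63.30	M	0	0			0.41	
X1	nonliver	53.70	M	0	1			3.56	
X2	nonliver	54.90	F	0	0			0.27	
N1	normal_liver	25.30	M	0	0			1.95	
N2	normal_liver	79.70	M	0	1			6.86	
N3	normal_liver	33.00	M	0	1			0.66	
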