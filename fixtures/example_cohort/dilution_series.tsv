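assay_id	copies	cq
sense	100000.0	21.5136
sense	10000.0	24.6302
sense	1000.0	28.3391
sense	100.0	31.2086
sense	10.0	34.5557
antisense	100000.0	21.338
antisense	10000.0	24.8142
antisense	1000.0	27.8723
antisense	100.0	31.5203
antisense	10.0	34.5433
bs_actin	100000.0	21.5074
bs_actin	10000.0	24.9266
bs_actin	1000.0	27.8845
bs_actin	100.0	31.1924
bs_actin	10.0	34.7567
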