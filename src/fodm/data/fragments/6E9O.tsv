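label	start	end
TM1	28	62
TM2	64	94
TM3	96	114
TM4	118	148
TM5	152	182
TM6	184	206
CH1	216	226
CH2	245	253
TM7	254	276
TM8	291	321
TM9	324	349
TM10A	354	369
TM10B	375	380
TM11	384	414
TM12	416	438
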