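label	start	end
TM1	16	47
TM2	52	80
TM3	81	101
TM4	104	134
TM5	135	166
TM6	169	192
SH1	204	217
TM7A	218	234
TM7B	234	251
TM8	251	281
TM9	281	309
TM10	309	343
TM11	343	375
TM12	375	399
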