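label	start	end
TM1	16	47
TM2	52	80
TM3	81	104
EC1	118	121
TM4	126	155
TM5	156	187
TM6	190	220
IC1	223	228
IC3	247	261
TM7A	270	291
TM7B	293	305
TM8	310	337
TM9	342	366
TM10	369	399
TM11	402	440
TM12	442	461
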