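label	start	end
TM1	3	39
TM2	42	69
TM3	72	104
TM4	109	146
TM5	147	177
TM6	186	218
SH1	237	242
TM7A	243	255
TM7B	262	272
TM8	276	306
TM9	307	330
TM10	336	366
TM11	367	396
TM12	401	424
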