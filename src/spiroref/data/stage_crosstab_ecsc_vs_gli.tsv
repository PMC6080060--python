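stage	mild	moderate	severe	very_severe
mild	14	3	0	0
moderate	0	36	12	0
severe	0	0	38	2
very_severe	0	0	0	19
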