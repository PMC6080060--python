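stage	mild	moderate	severe	very_severe
mild	16	1	0	0
moderate	1	43	0	0
severe	0	4	38	0
very_severe	0	0	2	19
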