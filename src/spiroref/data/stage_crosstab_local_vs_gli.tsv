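stage	mild	moderate	severe	very_severe
mild	13	4	0	0
moderate	1	35	8	0
severe	0	0	42	0
very_severe	0	0	0	21
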