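probe_id	gene	chromosome	evidence_sex
221728_x_at	XIST	X	female
214218_s_at	XIST	X	female
201909_at	RPS4Y1	Y	male
205000_at	DDX3Y	Y	male
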