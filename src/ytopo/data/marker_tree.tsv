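marker	parent	major
M96	ROOT	E
M78	M96	E
M89	ROOT	F
M201	M89	G
P15	M201	G
M170	M89	I
M253	M170	I
P37	M170	I
M223	M170	I
M304	M89	J
M9	M89	K
M20	M9	L
M70	M9	T
M45	M9	P
M242	M45	Q
M173	M45	R
SRY_10831_	M173	R
M17	SRY_10831_	R
M343	M173	R
M269	M343	R
L23/S141	M269	R
M412/S167	L23/S141	R
L11/S127	M412/S167	R
U106/S21	L11/S127	R
S116	L11/S127	R
U152/S28	S116	R
M529/S145	S116	R
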