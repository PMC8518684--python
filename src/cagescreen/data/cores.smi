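*c1ccc2cc(*)ccc2c1	A
*c1ccc(*)cc1	B
*c1cccc(*)c1	C
*C#Cc1ccc(C#C*)cc1	D
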