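*c1ccncc1	1
*c1cccnc1	2
*c1cncc(C)c1	3
*c1cncc(OC)c1	4
*c1cnc2ccccc2c1	5
*c1cncc2ccccc12	6
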