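cycle	interphase_min	mitosis_min
8	4.2	5
9	5.5	5
10	7	5
11	9.5	5
12	12.5	5
13	15	5
14	65	5
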