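pos
1000
7000
8000
9000
10000
12000
18000
19000
20000
21000
23000
29000
30000
31000
32000
34000
40000
41000
42000
43000
45000
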