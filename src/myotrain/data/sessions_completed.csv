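participant,week1,week2,week3,week4
1,6,6,6,6
2,5,4,5,6
3,6,6,6,6
4,6,5,5,6
5,6,6,6,4
6,6,6,6,5
7,4,3,6,5
8,6,4,6,6
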