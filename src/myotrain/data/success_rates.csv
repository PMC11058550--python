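participant,tongue_baseline,tongue_post,lip_baseline,lip_post
1,34,82,38,80
2,73,47,78,51
3,61,99,90,95
4,53,79,69,89
5,62,90,92,97
6,73,95,80,97
7,92,95,91,90
8,79,92,88,95
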