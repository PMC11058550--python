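participant,ahi_pre,ahi_post
1,13.6,11.6
2,15.4,19.6
3,41.0,40.8
4,17.4,6.3
5,25.0,21.3
6,20.5,14.9
7,12.6,8.3
8,20.2,19.0
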