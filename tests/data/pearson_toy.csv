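x,y
1,2
2,1
4,5
5,4
7,8
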