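subject,t0,t5,t10
A,3,5,4
B,6,9,8
C,2,4,6
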