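5	4	10
u1	v1
u1	v2
u1	v4
u2	v1
u2	v2
u2	v4
u3	v3
u3	v4
u4	v4
u5	v4
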