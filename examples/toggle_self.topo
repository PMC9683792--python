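Source Target Type
A A 1
A B 2
B A 2
B B 1
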