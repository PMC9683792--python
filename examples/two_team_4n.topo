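Source Target Type
TF1 TF2 1
TF1 miRsyn1 2
TF1 miRsyn2 2
TF2 TF1 1
TF2 miRsyn1 2
TF2 miRsyn2 2
miRsyn1 TF1 2
miRsyn1 TF2 2
miRsyn1 miRsyn2 1
miRsyn2 TF1 2
miRsyn2 TF2 2
miRsyn2 miRsyn1 1
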