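Source Target Type
TF1 TF2 1
TF1 TF3 1
TF1 TF4 1
TF1 miRsyn2 2
TF1 miRsyn3 2
TF1 miRsyn4 2
TF2 TF3 1
TF2 TF4 1
TF2 miRsyn1 2
TF2 miRsyn3 2
TF2 OUT1 1
TF3 TF4 1
TF3 miRsyn1 2
TF3 miRsyn2 2
TF4 TF1 1
TF4 TF3 1
TF4 miRsyn1 2
TF4 miRsyn4 2
TF4 OUT2 2
miRsyn1 TF2 2
miRsyn1 TF4 2
miRsyn1 miRsyn2 1
miRsyn1 miRsyn4 1
miRsyn1 OUT1 2
miRsyn2 TF1 2
miRsyn2 miRsyn1 1
miRsyn2 miRsyn3 1
miRsyn3 TF2 2
miRsyn3 miRsyn2 1
miRsyn3 miRsyn4 1
miRsyn4 TF1 2
miRsyn4 TF2 2
miRsyn4 miRsyn1 1
miRsyn4 miRsyn3 1
miRsyn4 OUT2 1
SIG1 TF4 1
SIG1 miRsyn1 2
SIG2 TF4 2
SIG2 miRsyn4 1
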