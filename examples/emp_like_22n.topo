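Source Target Type
TF1 TF2 1
TF1 TF3 1
TF1 TF4 1
TF1 miRsyn2 2
TF1 miRsyn3 2
TF1 miRsyn4 2
TF1 OUT2 2
TF2 TF3 1
TF2 miRsyn5 2
TF3 TF4 1
TF3 miRsyn4 2
TF3 miRsyn5 2
TF4 TF1 1
TF4 TF2 1
TF4 TF3 1
TF4 TF5 1
TF4 TF6 1
TF4 TF8 1
TF4 miRsyn3 2
TF4 miRsyn5 2
TF4 OUT3 1
TF5 TF6 1
TF6 TF3 1
TF6 TF7 1
TF6 miRsyn1 2
TF6 miRsyn5 2
TF7 TF1 1
TF7 TF4 1
TF7 TF6 1
TF7 TF8 1
TF7 miRsyn2 2
TF7 miRsyn3 2
TF8 TF1 1
TF8 TF3 1
TF8 TF9 1
TF8 OUT4 2
TF9 TF1 1
TF9 TF4 1
TF9 TF6 1
TF9 miRsyn1 2
TF9 miRsyn2 2
TF9 miRsyn6 2
TF9 OUT1 1
miRsyn1 TF1 2
miRsyn1 miRsyn2 1
miRsyn1 miRsyn6 1
miRsyn2 TF7 2
miRsyn2 miRsyn1 1
miRsyn2 miRsyn3 1
miRsyn2 miRsyn6 1
miRsyn2 OUT2 1
miRsyn2 OUT4 1
miRsyn3 TF2 2
miRsyn3 TF4 2
miRsyn3 TF8 2
miRsyn3 TF9 2
miRsyn3 miRsyn4 1
miRsyn3 miRsyn6 1
miRsyn3 OUT1 2
miRsyn4 TF1 2
miRsyn4 TF2 2
miRsyn4 TF8 2
miRsyn4 TF9 2
miRsyn4 miRsyn3 1
miRsyn4 miRsyn5 1
miRsyn5 TF4 2
miRsyn5 TF5 2
miRsyn5 TF8 2
miRsyn5 miRsyn6 1
miRsyn5 OUT3 2
miRsyn6 TF1 2
miRsyn6 TF9 2
miRsyn6 miRsyn1 1
miRsyn6 miRsyn5 1
SIG1 TF7 1
SIG1 miRsyn3 2
SIG2 TF5 2
SIG2 miRsyn3 1
SIG3 TF6 1
SIG3 miRsyn1 2
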