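Cell_line,Inducer 1,Inducer 2,Inducer 3
BT20,54.961,55.145,63.318
BT474,95.609,96.487,79.182
BT549,51.413,69.378,65.539
HCC1143,74.919,79.182,96.487
HCC1937,60.041,80.197,75.877
HCC70,63.664,71.355,78.426
T47D,74.412,79.839,95.065
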