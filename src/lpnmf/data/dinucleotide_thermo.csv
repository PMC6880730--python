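dinucleotide,dG37,dH,dS
AA,-1.00,-7.9,-22.2
AC,-1.44,-8.4,-22.4
AG,-1.28,-7.8,-21.0
AT,-0.88,-7.2,-20.4
CA,-1.45,-8.5,-22.7
CC,-1.84,-8.0,-19.9
CG,-2.17,-10.6,-27.2
CT,-1.28,-7.8,-21.0
GA,-1.30,-8.2,-22.2
GC,-2.24,-9.8,-24.4
GG,-1.84,-8.0,-19.9
GT,-1.44,-8.4,-22.4
TA,-0.58,-7.2,-21.3
TC,-1.30,-8.2,-22.2
TG,-1.45,-8.5,-22.7
TT,-1.00,-7.9,-22.2
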