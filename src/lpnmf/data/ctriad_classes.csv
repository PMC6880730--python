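class,residues
1,AGV
2,ILFP
3,YMTS
4,HNQW
5,RK
6,DE
7,C
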