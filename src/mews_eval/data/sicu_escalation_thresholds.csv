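threshold,tp,tn,fp,fn
8,1,185,1,76
7,4,183,3,73
6,7,179,7,70
5,9,170,16,68
4,23,139,47,54
3,44,113,73,33
2,63,66,120,14
1,77,4,182,0
0,77,0,186,0
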