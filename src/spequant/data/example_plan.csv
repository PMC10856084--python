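run_id,x1,x2,x3,x4,x5,x6,x7,x8,x9,x10,x11
1,0.35,0.35,0.35,5,15,55,55,15,15,0,0
2,0.5,0.2,0.2,0,25,15,55,25,5,1,1
3,0.5,0.2,0.5,10,5,55,55,25,5,-1,-1
4,0.2,0.2,0.5,0,25,55,15,25,25,1,-1
5,0.2,0.5,0.2,10,25,15,55,25,25,-1,-1
6,0.35,0.35,0.35,5,15,55,55,15,15,0,0
7,0.35,0.35,0.35,5,15,55,55,15,15,0,0
8,0.5,0.5,0.2,10,25,55,15,5,5,1,-1
9,0.2,0.2,0.2,0,5,15,15,5,5,-1,-1
10,0.2,0.2,0.2,10,5,55,55,5,25,1,1
11,0.5,0.2,0.5,10,25,15,15,5,25,-1,1
12,0.2,0.5,0.5,0,25,55,55,5,5,-1,1
13,0.2,0.5,0.5,10,5,15,15,25,5,1,1
14,0.5,0.5,0.2,0,5,55,15,25,25,-1,1
15,0.5,0.5,0.5,0,5,15,55,5,25,1,-1
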