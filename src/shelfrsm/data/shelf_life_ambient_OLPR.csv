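run_id,packaging,rate,response_days
1,NONE,0.0,3.00
2,NONE,0.3,4.30
3,NONE,0.7,3.30
4,PBP,0.0,7.80
5,PBP,0.3,8.20
6,PBP,0.7,8.10
7,VBP,0.0,6.80
8,VBP,0.3,9.10
9,VBP,0.7,7.20
10,NONE,0.0,3.10
11,NONE,0.0,2.90
12,NONE,0.0,3.20
13,NONE,0.0,2.80
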