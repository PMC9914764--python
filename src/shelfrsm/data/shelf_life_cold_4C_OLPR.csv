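run_id,packaging,rate,response_days
1,NONE,0.0,5.00
2,NONE,0.3,7.10
3,NONE,0.7,6.40
4,PBP,0.0,20.20
5,PBP,0.3,22.90
6,PBP,0.7,21.80
7,VBP,0.0,21.70
8,VBP,0.3,23.90
9,VBP,0.7,22.80
10,NONE,0.0,5.40
11,NONE,0.0,5.60
12,NONE,0.0,5.80
13,NONE,0.0,6.00
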