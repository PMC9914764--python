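run_id,packaging,rate,response_days
1,NONE,0.0,3.00
2,NONE,0.3,4.00
3,NONE,0.7,3.70
4,PBP,0.0,8.00
5,PBP,0.3,7.70
6,PBP,0.7,7.20
7,VBP,0.0,7.00
8,VBP,0.3,6.60
9,VBP,0.7,5.00
10,NONE,0.0,2.90
11,NONE,0.0,3.10
12,NONE,0.0,2.80
13,NONE,0.0,3.20
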