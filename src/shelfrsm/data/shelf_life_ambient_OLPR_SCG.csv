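run_id,packaging,rate,response_days
1,NONE,0.0,3.00
2,NONE,0.17,4.20
3,NONE,0.33,4.70
4,PBP,0.0,7.90
5,PBP,0.17,8.40
6,PBP,0.33,9.10
7,VBP,0.0,6.90
8,VBP,0.17,7.30
9,VBP,0.33,7.90
10,NONE,0.0,3.10
11,NONE,0.0,2.90
12,NONE,0.0,3.20
13,NONE,0.0,2.80
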