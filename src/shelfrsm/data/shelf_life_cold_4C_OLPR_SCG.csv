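run_id,packaging,rate,response_days
1,NONE,0.0,5.00
2,NONE,0.17,7.20
3,NONE,0.33,7.60
4,PBP,0.0,20.20
5,PBP,0.17,23.20
6,PBP,0.33,24.80
7,VBP,0.0,21.70
8,VBP,0.17,24.30
9,VBP,0.33,26.10
10,NONE,0.0,5.40
11,NONE,0.0,5.60
12,NONE,0.0,5.80
13,NONE,0.0,6.00
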