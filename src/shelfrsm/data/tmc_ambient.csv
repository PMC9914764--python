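packaging,substrate_code,temperature,day,log_cfu_g
NONE,M1A,ambient,0,3.3
NONE,M1A,ambient,1,4.8
NONE,M1A,ambient,2,6.5
NONE,M1A,ambient,3,7.8
NONE,M1A,ambient,4,8.6
NONE,M1A,ambient,5,9.2
NONE,M1A,ambient,6,10.4
NONE,M1A,ambient,7,10.8
NONE,M1A,ambient,8,11.6
NONE,M1A,ambient,9,12.2
NONE,M1A,ambient,10,12.8
NONE,M1B,ambient,0,2.7
NONE,M1B,ambient,1,4.1
NONE,M1B,ambient,2,5.7
NONE,M1B,ambient,3,7.4
NONE,M1B,ambient,4,7.8
NONE,M1B,ambient,5,8.3
NONE,M1B,ambient,6,8.8
NONE,M1B,ambient,7,9.9
NONE,M1B,ambient,8,11.4
NONE,M1B,ambient,9,12.5
NONE,M1B,ambient,10,13.1
NONE,M1C,ambient,0,3.1
NONE,M1C,ambient,1,4.6
NONE,M1C,ambient,2,6.3
NONE,M1C,ambient,3,7.6
NONE,M1C,ambient,4,8.3
NONE,M1C,ambient,5,8.8
NONE,M1C,ambient,6,9.9
NONE,M1C,ambient,7,10.5
NONE,M1C,ambient,8,11.5
NONE,M1C,ambient,9,12.3
NONE,M1C,ambient,10,12.9
NONE,M2A,ambient,0,3.3
NONE,M2A,ambient,1,4.8
NONE,M2A,ambient,2,6.5
NONE,M2A,ambient,3,7.8
NONE,M2A,ambient,4,8.6
NONE,M2A,ambient,5,9.2
NONE,M2A,ambient,6,10.3
NONE,M2A,ambient,7,10.9
NONE,M2A,ambient,8,11.8
NONE,M2A,ambient,9,12.7
NONE,M2A,ambient,10,13.4
NONE,M2B,ambient,0,3.1
NONE,M2B,ambient,1,4.3
NONE,M2B,ambient,2,5.9
NONE,M2B,ambient,3,7.6
NONE,M2B,ambient,4,8.0
NONE,M2B,ambient,5,8.6
NONE,M2B,ambient,6,9.1
NONE,M2B,ambient,7,9.9
NONE,M2B,ambient,8,11.1
NONE,M2B,ambient,9,11.8
NONE,M2B,ambient,10,12.9
NONE,M2C,ambient,0,3.1
NONE,M2C,ambient,1,4.5
NONE,M2C,ambient,2,6.1
NONE,M2C,ambient,3,7.7
NONE,M2C,ambient,4,8.2
NONE,M2C,ambient,5,8.7
NONE,M2C,ambient,6,9.8
NONE,M2C,ambient,7,10.4
NONE,M2C,ambient,8,11.4
NONE,M2C,ambient,9,12.4
NONE,M2C,ambient,10,13.0
NONE,M3A,ambient,0,3.3
NONE,M3A,ambient,1,4.8
NONE,M3A,ambient,2,6.5
NONE,M3A,ambient,3,7.8
NONE,M3A,ambient,4,8.6
NONE,M3A,ambient,5,9.2
NONE,M3A,ambient,6,10.3
NONE,M3A,ambient,7,10.9
NONE,M3A,ambient,8,11.8
NONE,M3A,ambient,9,12.7
NONE,M3A,ambient,10,13.4
NONE,M3B,ambient,0,2.9
NONE,M3B,ambient,1,4.2
NONE,M3B,ambient,2,5.8
NONE,M3B,ambient,3,7.5
NONE,M3B,ambient,4,7.9
NONE,M3B,ambient,5,8.4
NONE,M3B,ambient,6,8.9
NONE,M3B,ambient,7,10.1
NONE,M3B,ambient,8,11.6
NONE,M3B,ambient,9,12.7
NONE,M3B,ambient,10,13.3
NONE,M3C,ambient,0,2.6
NONE,M3C,ambient,1,3.8
NONE,M3C,ambient,2,5.4
NONE,M3C,ambient,3,7.1
NONE,M3C,ambient,4,7.6
NONE,M3C,ambient,5,8.2
NONE,M3C,ambient,6,8.7
NONE,M3C,ambient,7,9.7
NONE,M3C,ambient,8,11.2
NONE,M3C,ambient,9,12.3
NONE,M3C,ambient,10,12.7
PBP,M1A,ambient,0,2.5
PBP,M1A,ambient,1,2.9
PBP,M1A,ambient,2,3.4
PBP,M1A,ambient,3,3.9
PBP,M1A,ambient,4,4.6
PBP,M1A,ambient,5,5.8
PBP,M1A,ambient,6,6.9
PBP,M1A,ambient,7,7.8
PBP,M1A,ambient,8,8.4
PBP,M1A,ambient,9,8.8
PBP,M1A,ambient,10,10.2
PBP,M1B,ambient,0,2.2
PBP,M1B,ambient,1,2.6
PBP,M1B,ambient,2,3.1
PBP,M1B,ambient,3,3.5
PBP,M1B,ambient,4,4.2
PBP,M1B,ambient,5,5.5
PBP,M1B,ambient,6,6.6
PBP,M1B,ambient,7,7.4
PBP,M1B,ambient,8,8.0
PBP,M1B,ambient,9,8.2
PBP,M1B,ambient,10,8.7
PBP,M1C,ambient,0,2.3
PBP,M1C,ambient,1,2.7
PBP,M1C,ambient,2,3.2
PBP,M1C,ambient,3,3.6
PBP,M1C,ambient,4,4.3
PBP,M1C,ambient,5,5.6
PBP,M1C,ambient,6,6.7
PBP,M1C,ambient,7,7.5
PBP,M1C,ambient,8,8.1
PBP,M1C,ambient,9,8.3
PBP,M1C,ambient,10,8.9
PBP,M2A,ambient,0,2.7
PBP,M2A,ambient,1,3.1
PBP,M2A,ambient,2,3.6
PBP,M2A,ambient,3,4.1
PBP,M2A,ambient,4,4.8
PBP,M2A,ambient,5,5.7
PBP,M2A,ambient,6,6.9
PBP,M2A,ambient,7,7.5
PBP,M2A,ambient,8,8.0
PBP,M2A,ambient,9,8.5
PBP,M2A,ambient,10,9.1
PBP,M2B,ambient,0,2.8
PBP,M2B,ambient,1,3.3
PBP,M2B,ambient,2,4.0
PBP,M2B,ambient,3,4.5
PBP,M2B,ambient,4,5.5
PBP,M2B,ambient,5,6.1
PBP,M2B,ambient,6,7.4
PBP,M2B,ambient,7,7.9
PBP,M2B,ambient,8,8.2
PBP,M2B,ambient,9,8.8
PBP,M2B,ambient,10,9.4
PBP,M2C,ambient,0,2.9
PBP,M2C,ambient,1,3.4
PBP,M2C,ambient,2,4.1
PBP,M2C,ambient,3,4.6
PBP,M2C,ambient,4,5.6
PBP,M2C,ambient,5,6.2
PBP,M2C,ambient,6,7.5
PBP,M2C,ambient,7,8.1
PBP,M2C,ambient,8,8.3
PBP,M2C,ambient,9,8.6
PBP,M2C,ambient,10,9.2
PBP,M3A,ambient,0,2.6
PBP,M3A,ambient,1,3.0
PBP,M3A,ambient,2,3.5
PBP,M3A,ambient,3,4.0
PBP,M3A,ambient,4,4.7
PBP,M3A,ambient,5,5.9
PBP,M3A,ambient,6,7.0
PBP,M3A,ambient,7,7.9
PBP,M3A,ambient,8,8.3
PBP,M3A,ambient,9,8.7
PBP,M3A,ambient,10,9.1
PBP,M3B,ambient,0,2.1
PBP,M3B,ambient,1,2.7
PBP,M3B,ambient,2,3.3
PBP,M3B,ambient,3,3.9
PBP,M3B,ambient,4,4.2
PBP,M3B,ambient,5,5.1
PBP,M3B,ambient,6,5.9
PBP,M3B,ambient,7,6.7
PBP,M3B,ambient,8,7.9
PBP,M3B,ambient,9,8.2
PBP,M3B,ambient,10,8.6
PBP,M3C,ambient,0,2.1
PBP,M3C,ambient,1,2.6
PBP,M3C,ambient,2,3.2
PBP,M3C,ambient,3,3.8
PBP,M3C,ambient,4,4.3
PBP,M3C,ambient,5,5.2
PBP,M3C,ambient,6,5.9
PBP,M3C,ambient,7,6.9
PBP,M3C,ambient,8,7.7
PBP,M3C,ambient,9,8.1
PBP,M3C,ambient,10,8.4
VBP,M1A,ambient,0,2.8
VBP,M1A,ambient,1,3.5
VBP,M1A,ambient,2,4.2
VBP,M1A,ambient,3,4.8
VBP,M1A,ambient,4,5.7
VBP,M1A,ambient,5,6.6
VBP,M1A,ambient,6,7.8
VBP,M1A,ambient,7,8.8
VBP,M1A,ambient,8,9.3
VBP,M1A,ambient,9,9.9
VBP,M1A,ambient,10,10.6
VBP,M1B,ambient,0,2.3
VBP,M1B,ambient,1,2.9
VBP,M1B,ambient,2,3.2
VBP,M1B,ambient,3,3.8
VBP,M1B,ambient,4,4.4
VBP,M1B,ambient,5,5.0
VBP,M1B,ambient,6,5.8
VBP,M1B,ambient,7,6.6
VBP,M1B,ambient,8,7.8
VBP,M1B,ambient,9,8.0
VBP,M1B,ambient,10,8.3
VBP,M1C,ambient,0,2.7
VBP,M1C,ambient,1,3.4
VBP,M1C,ambient,2,4.1
VBP,M1C,ambient,3,4.7
VBP,M1C,ambient,4,5.6
VBP,M1C,ambient,5,6.3
VBP,M1C,ambient,6,7.4
VBP,M1C,ambient,7,8.1
VBP,M1C,ambient,8,8.4
VBP,M1C,ambient,9,8.8
VBP,M1C,ambient,10,9.2
VBP,M2A,ambient,0,3.0
VBP,M2A,ambient,1,3.7
VBP,M2A,ambient,2,4.4
VBP,M2A,ambient,3,5.0
VBP,M2A,ambient,4,5.9
VBP,M2A,ambient,5,6.8
VBP,M2A,ambient,6,8.0
VBP,M2A,ambient,7,8.8
VBP,M2A,ambient,8,9.2
VBP,M2A,ambient,9,9.6
VBP,M2A,ambient,10,10.7
VBP,M2B,ambient,0,3.2
VBP,M2B,ambient,1,3.8
VBP,M2B,ambient,2,4.6
VBP,M2B,ambient,3,5.2
VBP,M2B,ambient,4,6.1
VBP,M2B,ambient,5,7.2
VBP,M2B,ambient,6,8.1
VBP,M2B,ambient,7,8.9
VBP,M2B,ambient,8,9.4
VBP,M2B,ambient,9,9.9
VBP,M2B,ambient,10,10.9
VBP,M2C,ambient,0,3.4
VBP,M2C,ambient,1,4.2
VBP,M2C,ambient,2,4.9
VBP,M2C,ambient,3,5.7
VBP,M2C,ambient,4,6.5
VBP,M2C,ambient,5,7.7
VBP,M2C,ambient,6,8.8
VBP,M2C,ambient,7,9.4
VBP,M2C,ambient,8,9.9
VBP,M2C,ambient,9,10.6
VBP,M2C,ambient,10,11.4
VBP,M3A,ambient,0,2.7
VBP,M3A,ambient,1,3.4
VBP,M3A,ambient,2,4.1
VBP,M3A,ambient,3,4.6
VBP,M3A,ambient,4,5.5
VBP,M3A,ambient,5,6.4
VBP,M3A,ambient,6,7.6
VBP,M3A,ambient,7,8.6
VBP,M3A,ambient,8,9.1
VBP,M3A,ambient,9,9.7
VBP,M3A,ambient,10,10.5
VBP,M3B,ambient,0,2.6
VBP,M3B,ambient,1,3.2
VBP,M3B,ambient,2,3.9
VBP,M3B,ambient,3,4.3
VBP,M3B,ambient,4,5.1
VBP,M3B,ambient,5,6.1
VBP,M3B,ambient,6,7.3
VBP,M3B,ambient,7,7.9
VBP,M3B,ambient,8,8.2
VBP,M3B,ambient,9,8.6
VBP,M3B,ambient,10,8.8
VBP,M3C,ambient,0,2.5
VBP,M3C,ambient,1,3.3
VBP,M3C,ambient,2,4.0
VBP,M3C,ambient,3,4.4
VBP,M3C,ambient,4,5.2
VBP,M3C,ambient,5,6.2
VBP,M3C,ambient,6,7.4
VBP,M3C,ambient,7,8.0
VBP,M3C,ambient,8,8.4
VBP,M3C,ambient,9,8.9
VBP,M3C,ambient,10,9.2
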