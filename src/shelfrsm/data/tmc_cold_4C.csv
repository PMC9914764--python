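packaging,substrate_code,temperature,day,log_cfu_g
NONE,M1A,cold_4C,0,4.1
NONE,M1A,cold_4C,5,6.5
NONE,M1A,cold_4C,6,8.4
NONE,M1A,cold_4C,7,8.6
NONE,M1A,cold_4C,15,13.1
NONE,M1A,cold_4C,20,14.2
NONE,M1A,cold_4C,21,14.5
NONE,M1A,cold_4C,22,14.8
NONE,M1A,cold_4C,23,15.4
NONE,M1A,cold_4C,24,15.8
NONE,M1A,cold_4C,27,16.5
NONE,M1B,cold_4C,0,3.6
NONE,M1B,cold_4C,5,5.6
NONE,M1B,cold_4C,6,7.3
NONE,M1B,cold_4C,7,8.1
NONE,M1B,cold_4C,15,12.3
NONE,M1B,cold_4C,20,13.5
NONE,M1B,cold_4C,21,13.9
NONE,M1B,cold_4C,22,14.4
NONE,M1B,cold_4C,23,14.9
NONE,M1B,cold_4C,24,15.7
NONE,M1B,cold_4C,27,16.2
NONE,M1C,cold_4C,0,3.7
NONE,M1C,cold_4C,5,5.9
NONE,M1C,cold_4C,6,7.8
NONE,M1C,cold_4C,7,8.4
NONE,M1C,cold_4C,15,12.8
NONE,M1C,cold_4C,20,13.8
NONE,M1C,cold_4C,21,14.2
NONE,M1C,cold_4C,22,14.7
NONE,M1C,cold_4C,23,15.2
NONE,M1C,cold_4C,24,15.8
NONE,M1C,cold_4C,27,16.4
NONE,M2A,cold_4C,0,4.1
NONE,M2A,cold_4C,5,6.5
NONE,M2A,cold_4C,6,8.4
NONE,M2A,cold_4C,7,8.8
NONE,M2A,cold_4C,15,13.4
NONE,M2A,cold_4C,20,14.8
NONE,M2A,cold_4C,21,15.2
NONE,M2A,cold_4C,22,15.8
NONE,M2A,cold_4C,23,16.7
NONE,M2A,cold_4C,24,17.4
NONE,M2A,cold_4C,27,17.9
NONE,M2B,cold_4C,0,3.6
NONE,M2B,cold_4C,5,5.7
NONE,M2B,cold_4C,6,7.5
NONE,M2B,cold_4C,7,8.2
NONE,M2B,cold_4C,15,12.4
NONE,M2B,cold_4C,20,13.7
NONE,M2B,cold_4C,21,14.1
NONE,M2B,cold_4C,22,14.6
NONE,M2B,cold_4C,23,15.0
NONE,M2B,cold_4C,24,15.9
NONE,M2B,cold_4C,27,16.3
NONE,M2C,cold_4C,0,3.8
NONE,M2C,cold_4C,5,5.9
NONE,M2C,cold_4C,6,7.9
NONE,M2C,cold_4C,7,8.5
NONE,M2C,cold_4C,15,13.0
NONE,M2C,cold_4C,20,14.0
NONE,M2C,cold_4C,21,14.3
NONE,M2C,cold_4C,22,14.6
NONE,M2C,cold_4C,23,15.3
NONE,M2C,cold_4C,24,15.5
NONE,M2C,cold_4C,27,16.0
NONE,M3A,cold_4C,0,4.1
NONE,M3A,cold_4C,5,6.5
NONE,M3A,cold_4C,6,8.4
NONE,M3A,cold_4C,7,8.8
NONE,M3A,cold_4C,15,13.3
NONE,M3A,cold_4C,20,14.6
NONE,M3A,cold_4C,21,15.1
NONE,M3A,cold_4C,22,15.6
NONE,M3A,cold_4C,23,16.5
NONE,M3A,cold_4C,24,17.3
NONE,M3A,cold_4C,27,17.8
NONE,M3B,cold_4C,0,3.5
NONE,M3B,cold_4C,5,5.5
NONE,M3B,cold_4C,6,7.2
NONE,M3B,cold_4C,7,8.1
NONE,M3B,cold_4C,15,11.8
NONE,M3B,cold_4C,20,12.5
NONE,M3B,cold_4C,21,13.3
NONE,M3B,cold_4C,22,13.9
NONE,M3B,cold_4C,23,14.1
NONE,M3B,cold_4C,24,14.5
NONE,M3B,cold_4C,27,15.1
NONE,M3C,cold_4C,0,3.4
NONE,M3C,cold_4C,5,5.3
NONE,M3C,cold_4C,6,6.9
NONE,M3C,cold_4C,7,7.8
NONE,M3C,cold_4C,15,11.6
NONE,M3C,cold_4C,20,12.3
NONE,M3C,cold_4C,21,12.8
NONE,M3C,cold_4C,22,13.4
NONE,M3C,cold_4C,23,13.9
NONE,M3C,cold_4C,24,14.2
NONE,M3C,cold_4C,27,14.9
PBP,M1A,cold_4C,0,1.4
PBP,M1A,cold_4C,5,2.5
PBP,M1A,cold_4C,6,3.7
PBP,M1A,cold_4C,7,4.2
PBP,M1A,cold_4C,15,6.5
PBP,M1A,cold_4C,20,7.8
PBP,M1A,cold_4C,21,8.4
PBP,M1A,cold_4C,22,8.8
PBP,M1A,cold_4C,23,9.4
PBP,M1A,cold_4C,24,9.8
PBP,M1A,cold_4C,27,10.2
PBP,M1B,cold_4C,0,1.2
PBP,M1B,cold_4C,5,1.9
PBP,M1B,cold_4C,6,2.6
PBP,M1B,cold_4C,7,3.5
PBP,M1B,cold_4C,15,5.8
PBP,M1B,cold_4C,20,7.7
PBP,M1B,cold_4C,21,7.9
PBP,M1B,cold_4C,22,8.0
PBP,M1B,cold_4C,23,8.2
PBP,M1B,cold_4C,24,8.6
PBP,M1B,cold_4C,27,9.8
PBP,M1C,cold_4C,0,1.3
PBP,M1C,cold_4C,5,2.1
PBP,M1C,cold_4C,6,2.8
PBP,M1C,cold_4C,7,3.7
PBP,M1C,cold_4C,15,6.0
PBP,M1C,cold_4C,20,7.6
PBP,M1C,cold_4C,21,8.1
PBP,M1C,cold_4C,22,8.3
PBP,M1C,cold_4C,23,8.7
PBP,M1C,cold_4C,24,9.4
PBP,M1C,cold_4C,27,10.0
PBP,M2A,cold_4C,0,1.4
PBP,M2A,cold_4C,5,2.5
PBP,M2A,cold_4C,6,3.7
PBP,M2A,cold_4C,7,4.2
PBP,M2A,cold_4C,15,6.5
PBP,M2A,cold_4C,20,7.8
PBP,M2A,cold_4C,21,8.4
PBP,M2A,cold_4C,22,8.9
PBP,M2A,cold_4C,23,9.4
PBP,M2A,cold_4C,24,10.2
PBP,M2A,cold_4C,27,10.9
PBP,M2B,cold_4C,0,1.2
PBP,M2B,cold_4C,5,1.9
PBP,M2B,cold_4C,6,2.6
PBP,M2B,cold_4C,7,3.5
PBP,M2B,cold_4C,15,5.8
PBP,M2B,cold_4C,20,7.4
PBP,M2B,cold_4C,21,7.9
PBP,M2B,cold_4C,22,8.2
PBP,M2B,cold_4C,23,8.7
PBP,M2B,cold_4C,24,9.2
PBP,M2B,cold_4C,27,9.9
PBP,M2C,cold_4C,0,1.3
PBP,M2C,cold_4C,5,2.0
PBP,M2C,cold_4C,6,2.7
PBP,M2C,cold_4C,7,3.6
PBP,M2C,cold_4C,15,5.9
PBP,M2C,cold_4C,20,7.5
PBP,M2C,cold_4C,21,8.0
PBP,M2C,cold_4C,22,8.2
PBP,M2C,cold_4C,23,8.7
PBP,M2C,cold_4C,24,9.2
PBP,M2C,cold_4C,27,9.9
PBP,M3A,cold_4C,0,1.4
PBP,M3A,cold_4C,5,2.5
PBP,M3A,cold_4C,6,3.7
PBP,M3A,cold_4C,7,4.2
PBP,M3A,cold_4C,15,6.5
PBP,M3A,cold_4C,20,7.8
PBP,M3A,cold_4C,21,8.4
PBP,M3A,cold_4C,22,8.9
PBP,M3A,cold_4C,23,9.4
PBP,M3A,cold_4C,24,10.2
PBP,M3A,cold_4C,27,10.9
PBP,M3B,cold_4C,0,1.1
PBP,M3B,cold_4C,5,1.7
PBP,M3B,cold_4C,6,2.4
PBP,M3B,cold_4C,7,3.3
PBP,M3B,cold_4C,15,4.9
PBP,M3B,cold_4C,20,6.2
PBP,M3B,cold_4C,21,6.7
PBP,M3B,cold_4C,22,7.3
PBP,M3B,cold_4C,23,7.9
PBP,M3B,cold_4C,24,8.2
PBP,M3B,cold_4C,27,8.6
PBP,M3C,cold_4C,0,1.0
PBP,M3C,cold_4C,5,1.5
PBP,M3C,cold_4C,6,2.2
PBP,M3C,cold_4C,7,3.1
PBP,M3C,cold_4C,15,4.7
PBP,M3C,cold_4C,20,5.9
PBP,M3C,cold_4C,21,6.6
PBP,M3C,cold_4C,22,7.2
PBP,M3C,cold_4C,23,7.7
PBP,M3C,cold_4C,24,8.0
PBP,M3C,cold_4C,27,8.8
VBP,M1A,cold_4C,0,1.4
VBP,M1A,cold_4C,5,2.6
VBP,M1A,cold_4C,6,3.8
VBP,M1A,cold_4C,7,4.3
VBP,M1A,cold_4C,15,6.5
VBP,M1A,cold_4C,20,7.9
VBP,M1A,cold_4C,21,8.5
VBP,M1A,cold_4C,22,9.0
VBP,M1A,cold_4C,23,9.5
VBP,M1A,cold_4C,24,10.3
VBP,M1A,cold_4C,27,11.0
VBP,M1B,cold_4C,0,1.1
VBP,M1B,cold_4C,5,1.6
VBP,M1B,cold_4C,6,2.3
VBP,M1B,cold_4C,7,3.2
VBP,M1B,cold_4C,15,4.7
VBP,M1B,cold_4C,20,6.0
VBP,M1B,cold_4C,21,6.5
VBP,M1B,cold_4C,22,7.1
VBP,M1B,cold_4C,23,7.7
VBP,M1B,cold_4C,24,8.2
VBP,M1B,cold_4C,27,8.7
VBP,M1C,cold_4C,0,1.2
VBP,M1C,cold_4C,5,2.0
VBP,M1C,cold_4C,6,2.7
VBP,M1C,cold_4C,7,3.6
VBP,M1C,cold_4C,15,5.9
VBP,M1C,cold_4C,20,7.7
VBP,M1C,cold_4C,21,7.9
VBP,M1C,cold_4C,22,8.0
VBP,M1C,cold_4C,23,8.2
VBP,M1C,cold_4C,24,8.7
VBP,M1C,cold_4C,27,9.6
VBP,M2A,cold_4C,0,1.4
VBP,M2A,cold_4C,5,2.6
VBP,M2A,cold_4C,6,3.8
VBP,M2A,cold_4C,7,4.3
VBP,M2A,cold_4C,15,6.5
VBP,M2A,cold_4C,20,7.9
VBP,M2A,cold_4C,21,8.5
VBP,M2A,cold_4C,22,9.0
VBP,M2A,cold_4C,23,9.5
VBP,M2A,cold_4C,24,10.3
VBP,M2A,cold_4C,27,10.9
VBP,M2B,cold_4C,0,1.1
VBP,M2B,cold_4C,5,1.7
VBP,M2B,cold_4C,6,2.4
VBP,M2B,cold_4C,7,3.3
VBP,M2B,cold_4C,15,4.9
VBP,M2B,cold_4C,20,6.2
VBP,M2B,cold_4C,21,6.7
VBP,M2B,cold_4C,22,7.3
VBP,M2B,cold_4C,23,7.9
VBP,M2B,cold_4C,24,8.2
VBP,M2B,cold_4C,27,8.6
VBP,M2C,cold_4C,0,1.2
VBP,M2C,cold_4C,5,2.0
VBP,M2C,cold_4C,6,2.7
VBP,M2C,cold_4C,7,3.6
VBP,M2C,cold_4C,15,5.9
VBP,M2C,cold_4C,20,7.7
VBP,M2C,cold_4C,21,7.9
VBP,M2C,cold_4C,22,8.0
VBP,M2C,cold_4C,23,8.2
VBP,M2C,cold_4C,24,8.7
VBP,M2C,cold_4C,27,9.4
VBP,M3A,cold_4C,0,1.4
VBP,M3A,cold_4C,5,2.6
VBP,M3A,cold_4C,6,3.8
VBP,M3A,cold_4C,7,4.3
VBP,M3A,cold_4C,15,6.5
VBP,M3A,cold_4C,20,7.9
VBP,M3A,cold_4C,21,8.5
VBP,M3A,cold_4C,22,9.0
VBP,M3A,cold_4C,23,9.5
VBP,M3A,cold_4C,24,10.3
VBP,M3A,cold_4C,27,10.9
VBP,M3B,cold_4C,0,1.0
VBP,M3B,cold_4C,5,1.5
VBP,M3B,cold_4C,6,2.3
VBP,M3B,cold_4C,7,3.2
VBP,M3B,cold_4C,15,4.7
VBP,M3B,cold_4C,20,5.8
VBP,M3B,cold_4C,21,6.6
VBP,M3B,cold_4C,22,7.2
VBP,M3B,cold_4C,23,7.7
VBP,M3B,cold_4C,24,8.1
VBP,M3B,cold_4C,27,8.7
VBP,M3C,cold_4C,0,1.0
VBP,M3C,cold_4C,5,1.3
VBP,M3C,cold_4C,6,1.8
VBP,M3C,cold_4C,7,2.4
VBP,M3C,cold_4C,15,4.2
VBP,M3C,cold_4C,20,5.1
VBP,M3C,cold_4C,21,5.9
VBP,M3C,cold_4C,22,6.5
VBP,M3C,cold_4C,23,6.9
VBP,M3C,cold_4C,24,7.5
VBP,M3C,cold_4C,27,8.3
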