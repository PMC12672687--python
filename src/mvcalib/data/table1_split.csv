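sample_id,role
1,calibration
2,calibration
3,calibration
4,calibration
5,calibration
6,calibration
7,calibration
8,calibration
9,validation
10,calibration
11,validation
12,calibration
13,calibration
14,calibration
15,calibration
16,calibration
17,calibration
18,validation
19,validation
20,validation
21,validation
22,validation
23,calibration
24,validation
25,calibration
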