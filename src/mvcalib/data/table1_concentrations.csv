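sample_id,SAF,HBD,HYD,OXD
1,13,3,4.5,9
2,13,1,2.5,13
3,3,1,6.5,7
4,3,5,3.5,13
5,23,2,6.5,9
6,8,5,4.5,7
7,23,3,3.5,7
8,13,2,3.5,11
9,8,2,5.5,13
10,8,4,6.5,11
11,18,5,5.5,9
12,23,4,4.5,13
13,18,3,6.5,13
14,13,5,6.5,5
15,23,5,2.5,11
16,23,1,5.5,5
17,3,4,2.5,9
18,18,1,4.5,11
19,3,3,5.5,11
20,13,4,5.5,7
21,18,4,3.5,5
22,18,2,2.5,7
23,8,1,3.5,9
24,3,2,4.5,5
25,8,3,2.5,5
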