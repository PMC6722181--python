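patient_id,gd_vol_1,gd_vol_2,tbr_max_1,tbr_max_2,os_months,pfs_months
1,0.9,4.3,2.6,,16.1,14.1
2,14.2,22.0,4.1,4.0,9.3,8.3
3,,14.8,3.5,4.6,5.6,5.1
4,6.0,3.7,3.6,2.8,22.8,9.4
5,31.6,5.2,4.1,3.4,6.9,5.4
6,0.6,2.7,3.6,3.0,28.5,7.2
7,6.1,0.5,4.6,3.2,28.5,19.3
8,0.0,0.0,2.0,1.7,14.8,13.9
9,1.3,6.4,2.3,3.2,9.3,4.7
10,1.1,0.6,3.7,2.3,16.1,5.3
11,16.8,8.7,3.3,3.3,2.8,2.8
12,1.6,0.9,2.2,1.5,28.7,28.7
13,5.2,,2.0,2.1,8.5,5.5
14,19.4,2.3,4.9,2.8,10.5,5.2
15,6.8,,3.6,2.5,14.8,10.3
16,19.5,3.9,4.8,3.8,14.3,3.3
17,8.2,0.4,3.3,2.6,15.4,12.9
18,0.8,6.2,3.1,2.5,9.8,7.8
19,1.3,6.9,3.8,2.4,20.9,9.3
20,2.2,0.6,3.1,2.5,8.2,6.6
21,4.9,4.6,2.9,2.6,9.9,5.8
22,3.7,2.8,2.4,2.8,13.8,3.8
23,0.1,1.8,2.4,2.0,15.7,15.7
24,6.5,,2.5,,6.8,5.2
25,6.4,0.0,2.0,1.4,13.3,13.3
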