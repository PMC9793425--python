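chromosome	length_cM
1	286.28
2	268.84
3	223.36
4	214.55
5	204.09
6	192.04
7	187.22
8	168.00
9	166.36
10	181.14
11	158.22
12	174.68
13	125.71
14	120.20
15	141.86
16	134.04
17	128.49
18	117.53
19	107.73
20	108.27
21	62.79
22	74.11
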