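dmu,s_minus_1.1.1,s_minus_2.1,s_minus_4,s_plus_5.1,s_plus_5.3
2,0.000,87.051,9.095,7.087,0.000
3,0.000,0.000,0.000,6.102,0.000
4,0.000,34.103,0.000,2.003,0.000
6,0.000,0.000,3.133,0.000,2.214
9,0.000,0.000,19.396,2.194,0.000
11,1.253,0.000,13.295,0.000,0.000
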