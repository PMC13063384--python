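dmu,oe,te,se,rts,s_minus,s_plus,efficiency
1,1,1,1,crs,0.000,0.000,Efficient
2,0.883,0.911,0.969,irs,96.146,7.087,Inefficient
3,0.858,1,0.858,drs,0.000,6.102,Inefficient
4,0.873,1,0.873,drs,0.000,0.000,Inefficient
5,1,1,1,crs,0.000,0.000,Efficient
6,0.997,1,0.997,drs,3.133,0.000,Inefficient
7,1,1,1,crs,0.000,0.000,Efficient
8,1,1,1,crs,0.000,0.000,Efficient
9,0.835,0.857,0.974,drs,19.396,2.194,Inefficient
10,1,1,1,crs,0.000,0.000,Efficient
11,0.850,0.893,0.952,irs,14.548,0.000,Inefficient
12,0.929,1,0.929,drs,58.190,6.217,Inefficient
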