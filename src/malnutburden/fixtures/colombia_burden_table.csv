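cycle,yll,yld,daly,daly_per_1000
1,9161.57,3942.97,13104.54,25.56
2,54245.38,10587.72,64833.10,126.48
3,57471.01,10820.21,68291.22,133.22
4,57394.77,11593.28,68988.04,134.58
Total,178272.73,36944.17,215216.89,419.84
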