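period,dli_mol_m2_d,day_14,day_18,day_21,day_25,day_28,day_32,day_35
November 1992,6.2,0.064,0.153,0.3,0.76,1.01,1.735,2.46
January 1993,4.7,0.063,0.141,0.2,0.44,0.84,1.2,1.87
February 1993,10.5,0.085,0.288,0.53,1.21,1.98,3.15,4.81
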