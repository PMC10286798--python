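treatment,source,label,dry_mass_g,pfd_umol_m2_s,i_par_fr_w_m2
1,study-2020a,R180,2.931,180.2,32.8
2,study-2020a,G60R120,2.745,184.3,36.3
3,study-2020a,B20R160,2.258,179.6,34.4
4,study-2020a,B20G60R100,2.449,180.2,37.2
5,study-2020a,B60R120(1),2.051,183.0,38.5
6,study-2020a,B60G60R60,1.527,178.7,40.3
7,study-2020a,WW180(1),2.470,184.8,36.5
8,study-2019,B30R150,0.046,183.7,36.2
9,study-2019,B30R150FR30,0.052,216.5,41.7
10,study-2019,R180FR30,0.045,214.2,38.4
11,study-2020b,B60R120(2),1.014,178.1,37.3
12,study-2020b,B40G20R120,1.187,182.5,37.3
13,study-2020b,B20G40R120,1.348,181.7,36.4
14,study-2020b,G60R120,1.587,184.3,36.3
15,study-2020b,B40R120FR20,1.232,180.8,36.1
16,study-2020b,B20R120FR40,1.438,183.6,34.4
17,study-2020b,R120FR60,1.622,174.2,30.1
18,study-2020b,B20G20R120FR20,1.417,182.4,35.4
19,study-2020b,WW180(2),1.394,188.1,37.0
20,study-2020b,EQW180,1.087,181.7,38.4
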