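run,time_h,volume_uL,cell_per_mm2,exosome_1e3_per_uL,glucose_mg_dL
1,6.46,186,3650,75,83.6
2,13.54,186,2700,178,35.2
3,6.46,363,3900,38,94.6
4,13.54,363,3500,72,55
5,5,275,3800,27,99
6,15,275,3400,123,50.6
7,10,150,2850,156,44
8,10,400,4000,55,88
9,10,275,3650,85,70.4
10,10,275,3500,80,68.2
11,10,275,3600,82,61.6
12,10,275,3500,77,74.8
13,10,275,3650,83,57.2
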