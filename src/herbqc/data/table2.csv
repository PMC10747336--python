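run,X1,X2,X3,CAGC,CAC,TSR,OD
1,8,60,40,0.107,0.385,0.3850,0.968
2,8,45,30,0.087,0.341,0.3634,0.887
3,9,45,40,0.110,0.414,0.3902,0.988
4,9,30,30,0.098,0.332,0.3930,0.937
5,8,45,30,0.091,0.322,0.3816,0.907
6,7,30,30,0.065,0.287,0.3342,0.000
7,7,45,40,0.076,0.245,0.3330,0.633
8,8,60,20,0.081,0.301,0.3712,0.856
9,9,45,20,0.098,0.337,0.3814,0.929
10,8,45,30,0.086,0.264,0.3722,0.825
11,8,30,20,0.071,0.265,0.3334,0.670
12,9,60,30,0.099,0.371,0.4042,0.967
13,8,45,30,0.081,0.319,0.3418,0.809
14,8,30,40,0.078,0.343,0.3654,0.864
15,7,60,30,0.069,0.254,0.3312,0.606
16,8,45,30,0.086,0.317,0.3688,0.878
17,7,45,20,0.087,0.239,0.3292,0.000
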