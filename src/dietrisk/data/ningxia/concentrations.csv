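category,metal,mean,sd,min,max,n,safe_limit
drinking_water,Al,0.0997,0.1342,0,0.5429,36,0.2
drinking_water,As,0.0056,0.0111,0,0.0456,36,0.01
drinking_water,Cr,0.0005,0.0006,0,0.0022,36,0.05
drinking_water,Cd,0.0,0.0001,0,0.0004,36,0.005
drinking_water,Cu,0.0012,0.0024,0,0.012,36,1.0
drinking_water,Ni,0.0054,0.0226,0,0.1361,36,0.02
drinking_water,Pb,0.0037,0.004,0,0.0121,36,0.01
drinking_water,Zn,0.0296,0.0549,0,0.2372,36,1.0
meat,Al,0.0202,0.0533,0,0.1613,8,10
meat,As,0.2183,0.1581,0,0.4269,8,0.5
meat,Cr,0.4719,0.4061,0,1.014,8,1.0
meat,Cd,0.0,0.0,0,0.0,8,0.1
meat,Cu,1.0747,0.5379,0.4116,2.2011,8,10
meat,Ni,0.0,0.0,0,0.0,8,0.2
meat,Pb,0.078,0.0816,0,0.196,8,0.2
meat,Zn,46.3887,19.4477,15.4314,73.5856,8,100
cereal,Al,0.0055,0.0388,0,0.3005,59,100
cereal,As,0.0158,0.0276,0,0.0989,59,0.5
cereal,Cr,0.2564,0.2363,0,0.7701,59,1.0
cereal,Cd,0.0128,0.0142,0,0.0656,59,0.1
cereal,Cu,0.282,0.2017,0,0.6861,59,10
cereal,Ni,0.1125,0.1987,0,1.2914,59,0.4
cereal,Pb,0.0453,0.0745,0,0.2835,59,0.2
cereal,Zn,5.3166,3.5065,0,12.1507,59,50
beans,Al,1.7096,1.148,0.398,4.1777,10,100
beans,As,0.0,0.0,0,0.0,10,0.5
beans,Cr,0.7536,0.8636,0.055,2.2808,10,1.0
beans,Cd,0.0045,0.0091,0,0.0301,10,0.2
beans,Cu,1.9198,1.7087,0.4282,4.6906,10,20
beans,Ni,0.4792,0.6002,0,1.6047,10,3.0
beans,Pb,0.4636,0.3877,0,1.0014,10,0.2
beans,Zn,8.5279,7.1609,1.7347,22.1708,10,100
potatoes,Al,0.4319,0.1784,0.1349,0.5866,4,10
potatoes,As,0.1475,0.1475,0,0.2984,4,0.2
potatoes,Cr,0.0322,0.0187,0.0155,0.0611,4,0.5
potatoes,Cd,0.0,0.0,0,0.0,4,0.1
potatoes,Cu,0.1316,0.0674,0.0287,0.2097,4,6
potatoes,Ni,0.1579,0.0683,0.0895,0.2639,4,0.3
potatoes,Pb,0.1798,0.1894,0,0.4436,4,0.2
potatoes,Zn,0.2276,0.3941,0,0.9102,4,5
solanaceous_fruit,Al,0.0872,0.118,0,0.359,34,10
solanaceous_fruit,As,0.0965,0.1237,0,0.3722,34,0.5
solanaceous_fruit,Cr,0.2728,0.2676,0,0.9064,34,0.5
solanaceous_fruit,Cd,0.0185,0.0262,0,0.1096,34,0.05
solanaceous_fruit,Cu,0.8822,0.8868,0.0885,3.3155,34,10
solanaceous_fruit,Ni,0.1461,0.1732,0,0.6618,34,0.3
solanaceous_fruit,Pb,0.1659,0.239,0,0.8709,34,0.1
solanaceous_fruit,Zn,5.3943,4.3754,0,15.8353,34,20
vegetables,Al,0.0064,0.0143,0,0.0549,18,10
vegetables,As,0.0042,0.0173,0,0.0753,18,0.5
vegetables,Cr,0.5642,0.4771,0.044,1.5511,18,0.5
vegetables,Cd,0.0277,0.0237,0,0.0722,18,0.2
vegetables,Cu,0.9527,0.9718,0.0197,2.8231,18,10
vegetables,Ni,0.556,0.9483,0,3.4651,18,0.3
vegetables,Pb,0.1603,0.4142,0,1.8107,18,0.3
vegetables,Zn,6.7956,5.574,1.3239,16.6289,18,20
fruit,Al,0.0171,0.0555,0,0.242,22,15
fruit,As,0.0473,0.1438,0,0.6893,22,0.5
fruit,Cr,0.0673,0.0303,0.0093,0.1172,22,0.5
fruit,Cd,0.0173,0.021,0,0.0759,22,0.05
fruit,Cu,0.3318,0.2118,0.1261,1.0795,22,10
fruit,Ni,0.2458,0.3922,0,1.5844,22,0.2
fruit,Pb,0.1496,0.2136,0,0.5846,22,0.1
fruit,Zn,4.4962,10.6937,0,50.6054,22,5
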