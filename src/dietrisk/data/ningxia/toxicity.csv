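metal,medium,rfd,sf
Al,water,1.0,
Al,food,0.0005,
As,water,0.0003,1.5
As,food,0.0003,1.5
Cr,water,0.003,
Cr,food,0.003,
Cd,water,0.005,
Cd,food,0.001,
Cu,water,0.04,
Cu,food,0.037,
Ni,water,0.02,
Ni,food,0.02,
Pb,water,0.0014,
Pb,food,0.0037,
Zn,water,0.3,
Zn,food,0.3,
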