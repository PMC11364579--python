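# US period life table 2017, total population, annual death probability qx.
# Transcribed (rounded) for the ages the 10-year model horizon touches.
age,qx
63,0.01174
64,0.01269
65,0.01373
66,0.01485
67,0.01602
68,0.01725
69,0.01864
70,0.02027
71,0.02215
72,0.02425
73,0.02659
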