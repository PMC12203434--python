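# Becke-Johnson rational damping parameters per density-functional preset.
# a2 in bohr. Published BJ-damping parameterizations for the CN-dependent
# dispersion correction.
# columns: preset,s6,s8,a1,a2,source
preset,s6,s8,a1,a2,source
PBE0,1.0,1.2177,0.4145,4.8593,D3BJ-params
B3LYP,1.0,1.9889,0.3981,4.4211,D3BJ-params
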