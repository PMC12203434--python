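# Constants of the smooth coordination-number counting function
#   f_count(r) = 1 / (1 + exp(-k1 * (k2*(Rcov_A + Rcov_B)/r - 1)))
# and of the Gaussian CN-interpolation weight exp(-k3 * dCN^2).
# Published constants of the CN-dependent dispersion model.
# columns: constant,value,source
constant,value,source
k1,16.0,D3-ref-data
k2,1.3333333333333333,D3-ref-data
k3,4.0,D3-ref-data
# cn_cutoff (angstrom, = 40 bohr): pairs beyond it contribute zero to CN,
# removing the 1/(1+e^k1) ~ 1e-7 asymptotic saturation of the logistic count.
cn_cutoff,21.16709322,D3-ref-data
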