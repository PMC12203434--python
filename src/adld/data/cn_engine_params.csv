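# Per-element auxiliary parameters of the CN-interpolated engine.
# r4r2: sqrt-expectation-value ratio entering C8 = 3*C6*r4r2_A*r4r2_B
#       (dimensionless tabulated form, adapted from published dispersion data).
# covalent_radius_A: single-bond covalent radii (angstrom), Pyykko-Atsumi.
# columns: element,r4r2,covalent_radius_A,source
element,r4r2,covalent_radius_A,source
H,2.00734898,0.32,D3-ref-data/Pyykko
Li,5.01974995,1.33,D3-ref-data/Pyykko
C,3.10492822,0.75,D3-ref-data/Pyykko
N,2.71175247,0.71,D3-ref-data/Pyykko
O,2.59361680,0.63,D3-ref-data/Pyykko
Ne,2.21522516,0.67,D3-ref-data/Pyykko
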