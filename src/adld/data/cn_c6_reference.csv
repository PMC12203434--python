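# Reference (coordination number, homoatomic C6) points for the CN-interpolated
# dispersion engine. C6 in hartree*bohr^6. Values adapted from the published
# reference data of the coordination-number-dependent semiclassical dispersion
# model family (TD-DFT hydride reference systems); this table is a compact,
# documented subset and makes no claim of bit-exact agreement with any
# published implementation.
# columns: element,cn_ref,c6_ref_au,source
element,cn_ref,c6_ref_au,source
H,0.0000,7.5916,D3-ref-data
H,0.9118,3.0267,D3-ref-data
Li,0.0000,1163.4500,D3-ref-data
Li,0.9865,85.0600,D3-ref-data
C,0.0000,49.1100,D3-ref-data
C,0.9868,43.2500,D3-ref-data
C,1.9985,29.3600,D3-ref-data
C,2.9987,25.7800,D3-ref-data
C,3.9844,18.2100,D3-ref-data
N,0.0000,25.2700,D3-ref-data
N,0.9944,19.6800,D3-ref-data
N,2.0143,15.5800,D3-ref-data
N,2.9903,12.8200,D3-ref-data
O,0.0000,15.5100,D3-ref-data
O,0.9925,12.8200,D3-ref-data
O,1.9887,10.3700,D3-ref-data
Ne,0.0000,6.2800,D3-ref-data
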