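# Static dipole polarizabilities (angstrom^3) and first ionization energies (eV)
# for the London-formula dispersion engine. "species" may be a neutral element
# symbol or an ion label (e.g. Li+). Polarizabilities: CRC Handbook compilation
# of experimental/recommended atomic values; ionization energies: NIST ASD.
# Note alpha(Li) - alpha(Li+) = 24.30 angstrom^3, a 99.9% decrease.
# columns: species,polarizability_A3,ionization_eV,source
species,polarizability_A3,ionization_eV,source
H,0.667,13.5984,CRC/NIST
Li,24.33,5.3917,CRC/NIST
Li+,0.0285,75.6400,CRC/NIST
C,1.76,11.2603,CRC/NIST
N,1.10,14.5341,CRC/NIST
O,0.802,13.6181,CRC/NIST
Ne,0.396,21.5645,CRC/NIST
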