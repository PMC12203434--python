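# Standard atomic weights (amu), IUPAC 2021 abridged values.
# Conventional single values are used for elements with interval weights.
# columns: element,mass_amu,source
element,mass_amu,source
H,1.008,IUPAC-2021
He,4.0026,IUPAC-2021
Li,6.94,IUPAC-2021
Be,9.0122,IUPAC-2021
B,10.81,IUPAC-2021
C,12.011,IUPAC-2021
N,14.007,IUPAC-2021
O,15.999,IUPAC-2021
F,18.998,IUPAC-2021
Ne,20.180,IUPAC-2021
Na,22.990,IUPAC-2021
S,32.06,IUPAC-2021
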