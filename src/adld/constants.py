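"""Fixed physical conversion constants (CODATA).

The public API works in angstrom and kcal/mol; the dispersion engines and
the cube writer work in Hartree atomic units. These constants are the only
place the two unit systems meet.
"""

BOHR_PER_ANGSTROM = 1.8897261254578281
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

HARTREE_TO_KCALMOL = 627.5094740631
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL

EV_TO_HARTREE = 1.0 / 27.211386245988

# alpha: angstrom^3 -> bohr^3
A3_TO_BOHR3 = BOHR_PER_ANGSTROM**3
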