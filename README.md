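# adld — atomic decomposition of London dispersion energy

London dispersion is the attractive force arising from correlated
instantaneous dipole fluctuations; its leading pair term falls off as
−C₆/r⁶. It is decisive in molecular recognition, conformational equilibria
and crystal packing, yet it is usually reported only as a single total
energy. `adld` decomposes that total into **per-atom contributions**
ε_A^disp, so that the spatial origin of dispersion stabilization can be
quantified, visualized and compared between structures.

For any atom-pairwise dispersion model the assignment is exact: each atom
receives half of every pair energy it participates in,

    ε_A = ½ Σ_{B≠A} E_AB,        Σ_A ε_A = E_disp(total).

On top of this the package provides:

* **Two pairwise engines** — a London-formula model
  (C₆ = 3/2 · α_A α_B · I_A I_B/(I_A+I_B) from packaged polarizabilities and
  ionization energies) and a coordination-number-dependent C₆ model with a
  C₈ term and Becke–Johnson rational damping
  (E = −s₆C₆/(r⁶+f₀⁶) − s₈C₈/(r⁸+f₀⁸), f₀ = a₁√(C₈/C₆)+a₂).
* **Charge sensitivity** — a pluggable scaler ζ(q) that damps
  polarizabilities / C₆ with atomic partial charge; the default exponential
  form is calibrated so the packaged α(Li)·ζ(+1) reproduces α(Li⁺), whose
  tabulated drop of 24.3 Å³ (99.9 %) drives the qualitative Li vs Li⁺
  contrast.
* **Fragment analysis** — per-fragment sums and the exact supramolecular
  split E_tot = E₁ + E₂ + E_int of a dimer into monomer-internal and
  interaction parts (pair-classified or isolated-monomer conventions).
* **Dispersion densities** — Gaussian-smeared scalar fields
  ρ_disp(r) = (α/π)^{3/2} Σ_A ε_A e^{−α(r−R_A)²} and difference densities
  Δρ_disp between mapped structures, written as Gaussian cube files for any
  standard viewer.
* **Mass-scaling analysis** — regressions of dimer dispersion energies
  against M₁M₂/R (the "gravitational-like" law) and against M₁²+M₂²
  (the generalized law E_tot = β(M₁²+M₂²)+γ), plus diagnostics for the
  intramolecular, interaction and mass-sum correlates.
* **External results** — per-atom contributions computed elsewhere (e.g.
  from a local energy decomposition of coupled-cluster calculations) are
  consumed via a documented CSV interchange table, so the fragment and
  density tooling is engine-agnostic.

## Worked example

```python
import numpy as np
from adld import (Atom, Molecule, total_dispersion, atomic_contributions,
                  supramolecular_split)
from adld.fixtures import make_ring, make_hetero_dimer

ring = make_ring(6, "C", 1.39)              # benzene-like carbon scaffold
li = Molecule([Atom("Li", np.zeros(3))])
complex_ = make_hetero_dimer(ring, li, r=2.5)   # Li 2.5 A above the ring

pairs, total = total_dispersion(complex_, engine="cnd", damping="PBE0")
acs = atomic_contributions(pairs, complex_, provenance="cnd")
print(f"total {total:.4f}")
print(f"eps(Li) {acs.eps[-1]:.4f}")

split = supramolecular_split(complex_, engine="cnd", convention="pair-classified")
print(f"E1 {split.e1:.4f}  E2 {split.e2:.4f}  E_int {split.e_int:.4f}")
```

prints

```
total -4.8869
eps(Li) -0.7894
E1 -3.3081  E2 0.0000  E_int -1.5788
```

All energies are kcal/mol and negative (stabilizing). The ring's internal
dispersion (E1 = −3.31) and the ring–lithium cross terms (E_int = −1.58)
make up the total; the lone Li atom has no internal pairs (E2 = 0) and is
assigned ε_Li = −0.79 — exactly half of E_int, since every pair it
participates in crosses the fragment boundary.
Setting a partial charge of +1 on Li with the default scaler collapses its
contribution by ~97 %, mirroring the drastic polarizability loss of the
cation.

The same pipelines are scriptable from the shell:

```sh
adld fixtures --out fx --seed 1          # synthetic 8-dimer benchmark
adld energy fx/homo-1.xyz                # total dispersion energy
adld atoms fx/homo-1.xyz --output eps.csv
adld split fx/hetero-6.xyz               # E1 / E2 / E_int
adld density fx/homo-1.xyz --output rho.cube --alpha 0.5
adld massfit fx --output fits.json       # mass-scaling regressions
```

## Layout

```
src/adld/geometry.py    atoms, molecules, fragments, XYZ + config I/O
src/adld/engines.py     London and CN-dependent pairwise engines, BJ damping,
                        charge scaler
src/adld/partition.py   atomic/fragment contributions, supramolecular split,
                        delta contributions, interchange table
src/adld/density.py     dispersion (difference) densities, cube I/O
src/adld/massfit.py     dimer records and mass-scaling regressions
src/adld/fixtures.py    seeded synthetic geometries and the dimer benchmark
src/adld/cli.py         `adld` command-line entry point
src/adld/data/          parameter tables (masses, polarizabilities, C6
                        reference data, damping presets) with sources
docs/methods.md         model assumptions, parameter choices, limitations
```
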