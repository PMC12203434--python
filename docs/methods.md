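# Methods

## The decomposition

For an atom-pairwise dispersion model, E_disp = Σ_{A<B} E_AB, the atomic
contribution of atom A is defined as half of every pair term it enters,

    ε_A = ½ Σ_{B≠A} E_AB.

This is exact by construction (Σ_A ε_A = E_disp identically) and mirrors
the half-assignment of electron-pair correlation energies to single
electrons used in local energy decompositions of coupled-cluster
dispersion: the atom plays the role the electron plays there, and the
atom-pair energy the role of the electron-pair energy. Orbital population
weights are not computed in this package; externally computed per-atom
contributions (for instance coupled-cluster/LED-derived ones) enter
pre-mapped to atoms through the CSV interchange table and flow through the
same fragment, difference and density machinery.

Fragment contributions are plain sums of ε_A over named atom groups. For a
two-fragment system the supramolecular split E_tot = E₁ + E₂ + E_int is
offered in two conventions:

* **pair-classified** — every pair term of the full system is assigned to
  within-1, within-2, or crossing; the identity holds exactly as summed.
* **isolated-monomer** — E₁ and E₂ are recomputed on each monomer alone and
  E_int is the remainder. Monomer coordinates are frozen at the in-dimer
  geometry (no re-optimization). For environment-dependent engines the two
  conventions differ by the coordination-number shift the partner induces;
  for the London engine they coincide to rounding.

Difference contributions Δε_A between two structures require a one-to-one,
element-preserving atom mapping; results are anchored to the first
structure's coordinates by default (an `anchor="second"` switch exists,
since neither choice is canonical).

## Engines

**London engine.** C₆ = 3/2 · α_A α_B · I_A I_B/(I_A+I_B) from packaged
static dipole polarizabilities (Å³) and first ionization energies (eV);
C₈ = 0. This engine is deliberately environment-free: its C₆ depends only
on the element, which makes it the reference for tests that require exact
separability.

**CN engine.** A coordination-number-dependent C₆ model: the smooth count
CN_A = Σ_B 1/(1+exp(−k₁(k₂(R_A+R_B)/r−1))) (k₁ = 16, k₂ = 4/3, covalent
radii from the packaged table) selects among per-element reference
(CN, C₆) points by Gaussian weights exp(−k₃ΔCN²), k₃ = 4; heteroatomic
reference values are geometric means of the homoatomic ones. The C₈ term
uses the tabulated √⟨r⁴⟩/⟨r²⟩ factors, C₈ = 3 C₆ r₄r₂(A) r₄r₂(B). Pairs
beyond 40 bohr contribute zero to the CN sum; without that cutoff the
logistic count saturates at 1/(1+e^k₁) ≈ 1.1·10⁻⁷ per pair, which is large
enough to contaminate the isolated-monomer split of widely separated
dimers. The parameter tables are shipped as commented CSV files with
per-value sources; they are adapted from the published reference data of
the CN-dependent semiclassical dispersion family and make no claim of
bit-exact agreement with any distributed implementation (reproducing such
binaries is a non-goal).

Both engines use Becke–Johnson rational damping,
E_AB = −s₆C₆/(r⁶+f₀⁶) − s₈C₈/(r⁸+f₀⁸) with f₀ = a₁√(C₈/C₆)+a₂, which is
finite at r → 0. Damping presets (PBE0, B3LYP) live in the parameter file.
Internal arithmetic is in Hartree atomic units; the API is Å and kcal/mol
(1 hartree = 627.5094740631 kcal/mol, 1 Å = 1.8897261254578281 bohr, both
fixed). Dispersion energies are negative throughout; "a contribution
decreases" always means its magnitude shrinks. The three-body
(Axilrod–Teller–Muto) term is omitted: the analyses this package supports
are two-body decompositions, and a three-body term has no unambiguous
pair assignment. No distance cutoff is applied to the energy sums by
default (systems are desk-scale); an optional `cutoff` argument exists.

## Charge sensitivity

Charge dependence enters through a pluggable scaler contract:
`scale(v, 0) = v` exactly, strictly decreasing in q for q > 0, strictly
positive over the physical charge range. The default implementation is a
single-parameter exponential, ζ(q) = e^{−bq}, applied to polarizabilities
(London engine) or as the symmetric per-atom pair factor √(ζ_A ζ_B) on C₆
(CN engine, with C₈ rebuilt from the scaled C₆). The decay constant is
calibrated once against the packaged table so that α(Li)·ζ(+1) = α(Li⁺);
the tabulated drop α(Li) − α(Li⁺) = 24.3 Å³ (99.9 %) is what makes the
Li → Li⁺ contrast so drastic. The scaler is smooth in q and r by design:
the short-range non-smoothness that environment-coupled charge models can
show (abrupt C₆ changes along a dissociation curve) is not emulated.
Without a scaler both engines are charge-blind by construction — the
geometry-only model's insensitivity to charge state is a structural
property, not an approximation error.

## Dispersion density

ρ_disp(r) = N(α) Σ_A ε_A e^{−α(r−R_A)²} on an axis-aligned uniform grid
covering the atomic bounding box plus padding. The default prefactor is
the normalizing Gaussian constant N = (α/π)^{3/2}, chosen so each atomic
term integrates analytically to ε_A and the field to the total energy;
the alternative (πα)^{−3/2} convention seen in some prints equals the
normalizing form only at α = 1 and is available behind a
`paper_prefactor` flag purely to reproduce figure scales. α is interpreted
in Å⁻² (coordinates are Å); defaults are 0.5 for single-structure maps and
0.3 for difference maps, the values typically used for visualization.
Grid defaults: 0.2 Å spacing, 4.0 Å padding; a guard refuses grids beyond
512³ points unless overridden. Cube files are written in Bohr with
z-fastest value ordering per the Gaussian cube convention; isosurface
rendering is left to standard viewers.

## Mass-scaling analysis

Each dimer yields a record (E_tot, E₁, E₂, E_int, M₁, M₂, R) via the
supramolecular split, standard-atomic-weight masses and center-of-mass
separation. All fits are ordinary least squares with an intercept (a
`--no-intercept` flag exists; the generalized law's γ is a real physical
offset absorbing mean intermolecular contributions, so the intercept is
kept by default), with R² = 1 − SS_res/SS_tot about the mean. A
zero-variance predictor raises; a zero-variance response reports R² = 0
with a warning, because the interaction fit is used precisely as a
non-correlation diagnostic. Units: β in kcal/(mol·amu²), γ in kcal/mol.

The rationale connecting the laws: for compact monomers whose interatomic
distances vary within a narrow range, E₁ ∝ (Σ_A α_A)² ∝ M₁², since atomic
polarizability tracks atomic mass. Hence E_tot ≈ β(M₁²+M₂²)+γ, which
collapses to the M₁M₂/R law only when M₁ = M₂ (then M₁²+M₂² = 2M₁M₂ and R
varies little). `compact_cluster_check` quantifies the premise directly by
reporting E₁/(Σα)² across a cluster family and its relative spread.

## Synthetic fixtures

All test inputs are generated: rings, chains, regular simplices,
Fibonacci-sphere shells, seeded rejection-sampled random clusters, and an
8-dimer benchmark (five equal-mass homodimers of carbon shells with 8–24
atoms per monomer at 2.5 Å shell radius, centers 7.0–8.2 Å apart, plus
three hetero dimers whose monomer masses differ by at least 3×, with a
0.05 Å seeded coordinate jitter). The shells emulate the one feature the
mass-law argument needs — compact monomers of graded mass with bounded
interatomic distances and mildly varying R — and deliberately not the
chemistry of real dimer sets (no hydrogens, no bonding topology, no
relaxed geometries). Passing the R² ordering checks therefore shows the
structural mechanism (equal-mass collapse vs asymmetric break) in the
pairwise model, not agreement with any published R² values, which would
require the original dimer geometries and reference energies. Problem
sizes throughout the suite (clusters of 3–50 atoms, 10⁵–10⁶-point grids,
8-dimer fits) were chosen as the smallest that exercise every code path
with comfortable numerical headroom.

## Numerical choices and degenerate inputs

* Counting-function exponent clipped at ±50 before exponentiation
  (overlapping atoms, huge separations).
* BJ energies are finite at r → 0; r ≤ 0 raises.
* `c6_interpolated` weights always normalize (a single reference point
  returns that C₆ for any CN).
* Pair matrices are validated (symmetry, zero diagonal, finiteness) at
  construction; conservation checks use 1e-10 relative tolerance, the
  half-sum oracle 1e-14.
* Fragment configs win over XYZ comment-line fragment tags on conflict,
  with a logged warning; atom indices are 0-based internally, 1-based in
  all user-facing text.
* Mass table: IUPAC standard atomic weights (conventional values for
  interval elements); isotopes out of scope.

## Known limitations

* Supported elements are those in the packaged tables (H, C, N, O, Li, Ne
  for the engines; a few more in the mass table). The tables are plain CSV
  and user-extensible.
* No three-body term, no periodic boundary conditions, no self-consistent
  charge model; partial charges are user-supplied inputs.
* The London engine ignores the chemical environment entirely; the CN
  engine's reference data are a compact documented subset, adequate for
  decomposition analysis but not for reproducing any specific published
  total energies.
* Cube I/O supports axis-aligned orthogonal grids only.
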