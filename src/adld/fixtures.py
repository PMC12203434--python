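"""Deterministic synthetic-geometry generators.

Every analysis in this package is testable without external downloads:
rings, chains, spherical shells, regular simplices, random clusters and a
small dimer benchmark are generated here from explicit parameters and
seeds (same spec + seed -> bitwise-identical geometry).
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import Atom, Molecule, center_of_mass

__all__ = [
    "make_ring",
    "make_chain",
    "make_shell",
    "make_simplex",
    "make_dimer",
    "make_hetero_dimer",
    "make_cluster",
    "make_dimer_benchmark",
]


def make_ring(n: int, element: str = "C", radius: float = 1.39) -> Molecule:
    """Regular planar n-gon (xy-plane, centered at the origin).

    ``radius`` is the circumradius in angstrom; the benzene-like default
    gives 1.39 A nearest-neighbor distances for n = 6... almost: the
    circumradius of benzene IS 1.39 A, nearest neighbors sit at
    2*r*sin(pi/n).
    """
    if n < 2:
        raise ValueError(f"a ring needs at least 2 atoms, got {n}")
    atoms = []
    for k in range(n):
        theta = 2.0 * math.pi * k / n
        atoms.append(Atom(element, np.array([radius * math.cos(theta),
                                             radius * math.sin(theta), 0.0])))
    return Molecule(atoms=atoms)


def make_chain(n: int, element: str = "C", spacing: float = 1.5,
               axis: int = 2) -> Molecule:
    """Linear chain of n atoms along one Cartesian axis."""
    if n < 1:
        raise ValueError(f"a chain needs at least 1 atom, got {n}")
    atoms = []
    for k in range(n):
        pos = np.zeros(3)
        pos[axis] = k * spacing
        atoms.append(Atom(element, pos))
    return Molecule(atoms=atoms)


def make_shell(n: int, element: str = "C", radius: float = 2.5) -> Molecule:
    """n quasi-uniform points on a sphere (Fibonacci lattice).

    A compact homoatomic cluster whose interatomic distances are bounded by
    the fixed diameter — the regime in which the intramolecular dispersion
    energy grows as the square of the atom count.
    """
    if n < 1:
        raise ValueError(f"a shell needs at least 1 atom, got {n}")
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    atoms = []
    for k in range(n):
        z = 1.0 - (2.0 * k + 1.0) / n
        rho = math.sqrt(max(0.0, 1.0 - z * z))
        phi = 2.0 * math.pi * k / golden
        atoms.append(Atom(element, radius * np.array(
            [rho * math.cos(phi), rho * math.sin(phi), z])))
    return Molecule(atoms=atoms)


def make_simplex(n: int, element: str = "Ne", edge: float = 3.0) -> Molecule:
    """Regular simplex: n <= 4 atoms at pairwise-equal distances ``edge``."""
    if not 1 <= n <= 4:
        raise ValueError(f"a regular simplex supports 1..4 atoms, got {n}")
    unit = [
        np.array([0.0, 0.0, 0.0]),
        np.array([1.0, 0.0, 0.0]),
        np.array([0.5, math.sqrt(3.0) / 2.0, 0.0]),
        np.array([0.5, math.sqrt(3.0) / 6.0, math.sqrt(6.0) / 3.0]),
    ]
    return Molecule(atoms=[Atom(element, edge * unit[k]) for k in range(n)])


def _place_pair(mol_a: Molecule, mol_b: Molecule, r: float, axis) -> Molecule:
    if r <= 0:
        raise ValueError(f"center-of-mass separation must be positive, got {r}")
    u = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("axis must be a nonzero vector")
    u = u / norm
    com_a = center_of_mass(mol_a)
    com_b = center_of_mass(mol_b)
    shift = com_a - com_b + r * u
    atoms = [Atom(a.element, a.position, a.charge) for a in mol_a.atoms]
    atoms += [Atom(a.element, a.position + shift, a.charge) for a in mol_b.atoms]
    labels = ["1"] * mol_a.n_atoms + ["2"] * mol_b.n_atoms
    return Molecule(atoms=atoms, fragment_labels=labels)


def make_dimer(monomer: Molecule, r: float, axis=(0.0, 0.0, 1.0)) -> Molecule:
    """Homodimer: two copies of ``monomer`` with centers of mass ``r`` apart.

    Fragments are labelled ``"1"`` and ``"2"``.
    """
    return _place_pair(monomer, monomer, r, axis)


def make_hetero_dimer(mol_a: Molecule, mol_b: Molecule, r: float,
                      axis=(0.0, 0.0, 1.0)) -> Molecule:
    """Two different monomers with centers of mass ``r`` apart."""
    return _place_pair(mol_a, mol_b, r, axis)


def make_cluster(n: int, element: str = "C", min_dist: float = 1.5,
                 box: float = 8.0, seed: int = 0,
                 max_attempts: int = 10000) -> Molecule:
    """Rejection-sampled random cluster in a cubic box.

    All pairwise distances are >= ``min_dist``; raises ``RuntimeError``
    after ``max_attempts`` failed placements (packing infeasible).
    """
    if n < 1:
        raise ValueError(f"cluster size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        candidate = rng.uniform(0.0, box, size=3)
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} atoms with min_dist={min_dist} in a "
                f"{box} A box after {max_attempts} attempts"
            )
        if all(np.linalg.norm(candidate - p) >= min_dist for p in placed):
            placed.append(candidate)
    return Molecule(atoms=[Atom(element, p) for p in placed])


def make_dimer_benchmark(seed: int = 0) -> list[tuple[str, Molecule, str, str]]:
    """Synthetic 8-dimer set for the mass-scaling analysis.

    Five equal-mass homodimers of compact carbon shells of increasing size,
    plus three strongly mass-asymmetric hetero dimers (monomer masses
    differing by >= 3x). Center-of-mass separations vary only mildly, the
    regime in which the gravitational-like law can hold for the equal-mass
    subset while the asymmetric trio breaks it. Coordinates carry a small
    seeded jitter so distinct seeds give distinct (but reproducible)
    geometries.
    """
    rng = np.random.default_rng(seed)

    def jitter(mol: Molecule, scale: float = 0.05) -> Molecule:
        moved = [Atom(a.element, a.position + rng.normal(0.0, scale, 3), a.charge)
                 for a in mol.atoms]
        return Molecule(atoms=moved, fragment_labels=list(mol.fragment_labels))

    out: list[tuple[str, Molecule, str, str]] = []
    homo_sizes = [8, 12, 16, 20, 24]
    homo_r = [7.0, 7.3, 7.6, 7.9, 8.2]
    for k, (n, r) in enumerate(zip(homo_sizes, homo_r), start=1):
        monomer = jitter(make_shell(n, "C", radius=2.5))
        out.append((f"homo-{k}", make_dimer(monomer, r), "1", "2"))
    hetero = [(4, 24, 7.4), (6, 30, 7.7), (8, 36, 8.0)]
    for k, (na, nb, r) in enumerate(hetero, start=6):
        mol_a = jitter(make_shell(na, "C", radius=2.5))
        mol_b = jitter(make_shell(nb, "C", radius=2.5))
        out.append((f"hetero-{k}", make_hetero_dimer(mol_a, mol_b, r), "1", "2"))
    return out
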