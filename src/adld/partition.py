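"""Atomic decomposition of the London dispersion energy (ADLD).

For an atom-pairwise model, each atom receives half of every pair energy it
participates in:

    eps_A = (1/2) * sum_{B != A} E_AB,    sum_A eps_A = E_tot.

This mirrors the electron-level half-assignment of pair correlation
energies in local energy decompositions: the atom plays the role of the
electron, the atom-pair energy that of the electron-pair energy. The same
containers carry externally computed per-atom contributions (e.g. coupled
cluster / LED-derived values) read from a delimited interchange table, so
that visualization and fragment analysis are engine-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engines import ChargeScaler, PairEnergyMatrix, total_dispersion
from .geometry import ATOMIC_NUMBERS, AtomMapping, Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "AtomicContributionSet",
    "FragmentContributionSet",
    "SupramolecularSplit",
    "DeltaContributionSet",
    "atomic_contributions",
    "fragment_contributions",
    "supramolecular_split",
    "delta_contributions",
    "read_contributions",
    "write_contributions",
]

_TABLE_COLUMNS = ["atom_index", "element", "x", "y", "z", "eps_kcalmol"]


@dataclass(frozen=True)
class AtomicContributionSet:
    """Per-atom dispersion contributions eps_A (kcal/mol) summing to the total."""

    molecule: Molecule
    eps: np.ndarray
    provenance: str = "external"

    def __post_init__(self) -> None:
        e = np.asarray(self.eps, dtype=float)
        if e.shape != (self.molecule.n_atoms,):
            raise ValueError(
                f"{e.size} contributions for {self.molecule.n_atoms} atoms"
            )
        if not np.all(np.isfinite(e)):
            raise ValueError("non-finite atomic contribution")
        object.__setattr__(self, "eps", e)

    @property
    def total(self) -> float:
        return float(self.eps.sum())

    def __add__(self, other: "AtomicContributionSet") -> "AtomicContributionSet":
        if other.molecule.n_atoms != self.molecule.n_atoms:
            raise ValueError("cannot add contribution sets of different sizes")
        return AtomicContributionSet(self.molecule, self.eps + other.eps,
                                     provenance=f"{self.provenance}+{other.provenance}")

    def to_frame(self) -> pd.DataFrame:
        """Interchange-table view (1-based indices, angstrom, kcal/mol)."""
        pos = self.molecule.positions
        return pd.DataFrame({
            "atom_index": np.arange(1, self.molecule.n_atoms + 1),
            "element": self.molecule.elements,
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
            "eps_kcalmol": self.eps,
        })


@dataclass(frozen=True)
class FragmentContributionSet:
    """Fragment-summed contributions; ``residual`` tracks conservation."""

    totals: dict[str, float]
    grand_total: float

    @property
    def residual(self) -> float:
        return self.grand_total - sum(self.totals.values())


@dataclass(frozen=True)
class SupramolecularSplit:
    """E_tot = E1 + E2 + E_int for a two-fragment system, kcal/mol.

    ``pair-classified``: every atom-pair energy of the dimer is classified as
    within fragment 1, within fragment 2, or crossing; the identity is exact
    by construction. ``isolated-monomer``: E1 and E2 are recomputed on each
    monomer alone (coordinates frozen at the in-dimer geometry) and
    E_int = E_tot - E1 - E2; for environment-dependent engines (CN-coupled
    C6) the two conventions differ by the monomer CN shift.
    """

    e1: float
    e2: float
    e_int: float
    e_tot: float
    convention: str
    fragments: tuple[str, str]


@dataclass(frozen=True)
class DeltaContributionSet:
    """Per-atom differences between two mapped structures, kcal/mol."""

    mapping: AtomMapping
    delta_eps: np.ndarray
    anchor: Molecule

    def __post_init__(self) -> None:
        d = np.asarray(self.delta_eps, dtype=float)
        if d.shape != (self.anchor.n_atoms,):
            raise ValueError("delta length does not match anchor molecule")
        object.__setattr__(self, "delta_eps", d)

    @property
    def total(self) -> float:
        return float(self.delta_eps.sum())


def atomic_contributions(pairs: PairEnergyMatrix, molecule: Molecule,
                         provenance: str = "pairwise") -> AtomicContributionSet:
    """Half-sum assignment: eps_A = 0.5 * sum_B E_AB."""
    if pairs.n_atoms != molecule.n_atoms:
        raise ValueError(
            f"pair matrix is {pairs.n_atoms}-atom but molecule has {molecule.n_atoms}"
        )
    eps = 0.5 * pairs.energies.sum(axis=1)
    return AtomicContributionSet(molecule, eps, provenance=provenance)


def fragment_contributions(acs: AtomicContributionSet,
                           molecule: Molecule | None = None) -> FragmentContributionSet:
    """Sum atomic contributions over the molecule's named fragments."""
    mol = molecule or acs.molecule
    if mol.n_atoms != acs.molecule.n_atoms:
        raise ValueError("molecule does not match the contribution set")
    totals = {
        frag: float(acs.eps[mol.fragment_indices(frag)].sum())
        for frag in mol.fragments
    }
    return FragmentContributionSet(totals=totals, grand_total=acs.total)


def supramolecular_split(
    molecule: Molecule,
    frag_a: str | None = None,
    frag_b: str | None = None,
    engine: str = "cnd",
    convention: str = "pair-classified",
    charges=None,
    scaler: ChargeScaler | None = None,
    damping="PBE0",
) -> SupramolecularSplit:
    """Split a two-fragment system's dispersion into E1 + E2 + E_int."""
    frags = molecule.fragments
    if frag_a is None and frag_b is None:
        if len(frags) != 2:
            raise ValueError(
                f"molecule has fragments {frags}; the supramolecular split needs "
                "exactly two — run it pairwise for multi-fragment systems"
            )
        frag_a, frag_b = frags
    assert frag_a is not None and frag_b is not None
    ia = molecule.fragment_indices(frag_a)
    ib = molecule.fragment_indices(frag_b)
    if set(ia.tolist()) | set(ib.tolist()) != set(range(molecule.n_atoms)):
        raise ValueError("the two fragments must cover every atom of the system")
    if convention not in ("pair-classified", "isolated-monomer"):
        raise ValueError(f"unknown convention {convention!r}")

    kw = dict(engine=engine, scaler=scaler, damping=damping)
    pairs, e_tot = total_dispersion(molecule, charges=charges, **kw)
    if convention == "pair-classified":
        e = pairs.energies
        e1 = float(np.triu(e[np.ix_(ia, ia)], k=1).sum())
        e2 = float(np.triu(e[np.ix_(ib, ib)], k=1).sum())
        e_int = e_tot - e1 - e2  # = sum of cross pairs, identity exact as summed
    else:
        def _monomer_total(idx: np.ndarray) -> float:
            sub = molecule.select(idx.tolist())
            sub_q = None if charges is None else np.asarray(charges, float)[idx]
            _, tot = total_dispersion(sub, charges=sub_q, **kw)
            return tot

        e1 = _monomer_total(ia)
        e2 = _monomer_total(ib)
        e_int = e_tot - e1 - e2
    return SupramolecularSplit(e1=e1, e2=e2, e_int=e_int, e_tot=e_tot,
                               convention=convention, fragments=(frag_a, frag_b))


def delta_contributions(acs_a: AtomicContributionSet, acs_b: AtomicContributionSet,
                        mapping: AtomMapping | None = None,
                        anchor: str = "first") -> DeltaContributionSet:
    """Per-atom difference Delta_eps_A = eps_A(first) - eps_mapped(A)(second).

    ``anchor`` selects whose coordinates carry the result ("first"/"second");
    differences are always first-minus-second.
    """
    mol_a, mol_b = acs_a.molecule, acs_b.molecule
    if mapping is None:
        mapping = AtomMapping.identity(mol_a.n_atoms)
    mapping.validate(mol_a, mol_b)
    pairs = np.array(mapping.pairs, dtype=int)
    delta = acs_a.eps - acs_b.eps[pairs]
    if anchor == "first":
        return DeltaContributionSet(mapping=mapping, delta_eps=delta, anchor=mol_a)
    if anchor == "second":
        inv = mapping.inverse()
        return DeltaContributionSet(
            mapping=mapping,
            delta_eps=delta[np.array(inv.pairs, dtype=int)],
            anchor=mol_b,
        )
    raise ValueError(f"anchor must be 'first' or 'second', got {anchor!r}")


# --------------------------------------------------------------------------
# Interchange table I/O (CSV dialect: '#' comments, '.' decimal, UTF-8)


def write_contributions(path: str | Path, acs: AtomicContributionSet) -> None:
    df = acs.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# ADLD atomic contributions; provenance={acs.provenance}; "
                 f"total_kcalmol={acs.total:.10f}\n")
        df.to_csv(fh, index=False, float_format="%.10f")


def read_contributions(path: str | Path,
                       molecule: Molecule | None = None) -> AtomicContributionSet:
    """Read an interchange table of per-atom contributions.

    Columns: atom_index (1-based), element, x, y, z (angstrom), eps_kcalmol.
    If ``molecule`` is given, elements must match and coordinates must agree
    within 1e-6 angstrom; otherwise the geometry is taken from the table.
    """
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; expected {_TABLE_COLUMNS}"
        )
    df = df.sort_values("atom_index")
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["atom_index"].to_numpy(), expected):
        raise ValueError(f"{path}: atom_index must be 1..{len(df)} with no gaps")
    bad = [el for el in df["element"] if el not in ATOMIC_NUMBERS]
    if bad:
        raise ValueError(f"{path}: unknown element(s) {sorted(set(bad))}")
    eps = df["eps_kcalmol"].to_numpy(dtype=float)
    table_pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    if molecule is not None:
        if list(df["element"]) != molecule.elements:
            raise ValueError(f"{path}: element sequence differs from the reference molecule")
        dev = np.abs(table_pos - molecule.positions).max()
        if dev > 1e-6:
            raise ValueError(
                f"{path}: coordinates deviate from the reference molecule by "
                f"{dev:.2e} angstrom (> 1e-6)"
            )
        mol = molecule
    else:
        from .geometry import Atom  # local to avoid polluting module surface
        mol = Molecule(atoms=[Atom(el, p) for el, p in zip(df["element"], table_pos)])
    return AtomicContributionSet(mol, eps, provenance="external")
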