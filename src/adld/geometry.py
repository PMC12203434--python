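"""Molecular geometry model: atoms, fragments, XYZ I/O and mass utilities.

Coordinates are angstrom everywhere at this surface. Atom indexing is
0-based internally; user-facing reports print 1-based indices. Fragments
are named groups of atom indices; a molecule with no explicit assignment
has every atom in fragment ``"1"``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .params import atomic_masses

logger = logging.getLogger(__name__)

__all__ = [
    "ATOMIC_NUMBERS",
    "Atom",
    "Molecule",
    "AtomMapping",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "read_fragment_config",
    "write_fragment_config",
    "molecular_mass",
    "center_of_mass",
    "com_distance",
]

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "S": 16,
}


class XYZParseError(ValueError):
    """Raised for malformed XYZ or fragment-config input."""


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol, position (angstrom) and optional charge (e)."""

    element: str
    position: np.ndarray
    charge: float = 0.0

    def __post_init__(self) -> None:
        if self.element not in ATOMIC_NUMBERS:
            raise ValueError(
                f"unknown element {self.element!r}; supported: "
                f"{sorted(ATOMIC_NUMBERS)}"
            )
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)

    @property
    def atomic_number(self) -> int:
        return ATOMIC_NUMBERS[self.element]


@dataclass
class Molecule:
    """An ordered list of atoms with per-atom fragment labels.

    Atom order is the canonical index used by every downstream quantity
    (pair matrices, contribution sets, interchange tables).
    """

    atoms: list[Atom]
    fragment_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Molecule needs at least one atom")
        if not self.fragment_labels:
            self.fragment_labels = ["1"] * len(self.atoms)
        if len(self.fragment_labels) != len(self.atoms):
            raise ValueError(
                f"{len(self.fragment_labels)} fragment labels for "
                f"{len(self.atoms)} atoms"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) array of coordinates in angstrom."""
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def fragments(self) -> list[str]:
        """Fragment names in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.fragment_labels:
            seen.setdefault(lab)
        return list(seen)

    def fragment_indices(self, fragment: str) -> np.ndarray:
        idx = np.array([i for i, lab in enumerate(self.fragment_labels) if lab == fragment],
                       dtype=int)
        if idx.size == 0:
            raise KeyError(f"fragment {fragment!r} not found; have {self.fragments}")
        return idx

    def select(self, indices: Iterable[int]) -> "Molecule":
        """Sub-molecule of the given atom indices (order preserved)."""
        idx = list(indices)
        return Molecule(
            atoms=[self.atoms[i] for i in idx],
            fragment_labels=[self.fragment_labels[i] for i in idx],
        )

    def with_charges(self, charges: Sequence[float]) -> "Molecule":
        q = np.asarray(charges, dtype=float)
        if q.shape != (self.n_atoms,):
            raise ValueError(f"expected {self.n_atoms} charges, got shape {q.shape}")
        return Molecule(
            atoms=[Atom(a.element, a.position, float(qi)) for a, qi in zip(self.atoms, q)],
            fragment_labels=list(self.fragment_labels),
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Molecule":
        """Rigidly transformed copy (rotation applied first)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return Molecule(
            atoms=[Atom(a.element, R @ a.position + t, a.charge) for a in self.atoms],
            fragment_labels=list(self.fragment_labels),
        )


@dataclass(frozen=True)
class AtomMapping:
    """One-to-one correspondence between the atoms of two molecules.

    ``pairs[i]`` is the index in molecule B mapped to atom ``i`` of molecule A.
    Mapped atoms must share the same element.
    """

    pairs: tuple[int, ...]

    @classmethod
    def identity(cls, n: int) -> "AtomMapping":
        return cls(tuple(range(n)))

    def validate(self, mol_a: Molecule, mol_b: Molecule) -> None:
        if len(self.pairs) != mol_a.n_atoms or mol_a.n_atoms != mol_b.n_atoms:
            raise ValueError(
                f"mapping covers {len(self.pairs)} atoms but molecules have "
                f"{mol_a.n_atoms} and {mol_b.n_atoms}"
            )
        if sorted(self.pairs) != list(range(mol_b.n_atoms)):
            raise ValueError("mapping is not a bijection onto the second molecule")
        for i, j in enumerate(self.pairs):
            ea, eb = mol_a.atoms[i].element, mol_b.atoms[j].element
            if ea != eb:
                raise ValueError(
                    f"mapped atoms differ in element: {ea}{i + 1} -> {eb}{j + 1}"
                )

    def inverse(self) -> "AtomMapping":
        inv = [0] * len(self.pairs)
        for i, j in enumerate(self.pairs):
            inv[j] = i
        return AtomMapping(tuple(inv))


# --------------------------------------------------------------------------
# XYZ I/O

_FRAG_COMMENT = re.compile(r"frags\s*=\s*(\S+)")


def _parse_index_spec(spec: str, n_atoms: int, context: str) -> list[int]:
    """Parse '1-6,9,11-12' (1-based, inclusive) into 0-based indices."""
    indices: list[int] = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo_s, hi_s = part.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(part)
        if not (1 <= lo <= hi <= n_atoms):
            raise XYZParseError(
                f"{context}: index range {part!r} outside 1..{n_atoms}"
            )
        indices.extend(range(lo - 1, hi))
    return indices


def _labels_from_spec(spec_pairs: list[tuple[str, str]], n_atoms: int,
                      context: str) -> list[str]:
    labels: list[str | None] = [None] * n_atoms
    for name, spec in spec_pairs:
        for i in _parse_index_spec(spec, n_atoms, context):
            if labels[i] is not None and labels[i] != name:
                raise XYZParseError(
                    f"{context}: atom {i + 1} assigned to both "
                    f"{labels[i]!r} and {name!r}"
                )
            labels[i] = name
    missing = [i + 1 for i, lab in enumerate(labels) if lab is None]
    if missing:
        raise XYZParseError(f"{context}: atoms {missing} not assigned to any fragment")
    return [str(lab) for lab in labels]


def read_fragment_config(path: str | Path, n_atoms: int) -> list[str]:
    """Read a sidecar fragment config: ``name = 1-6,9`` per line, '#' comments."""
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise XYZParseError(f"{path}:{lineno}: expected 'name = indices'")
        name, spec = (s.strip() for s in line.split("=", 1))
        if not name:
            raise XYZParseError(f"{path}:{lineno}: empty fragment name")
        pairs.append((name, spec))
    if not pairs:
        raise XYZParseError(f"{path}: no fragment definitions found")
    return _labels_from_spec(pairs, n_atoms, str(path))


def write_fragment_config(path: str | Path, molecule: Molecule) -> None:
    lines = ["# fragment config: name = 1-based atom indices"]
    for frag in molecule.fragments:
        idx = molecule.fragment_indices(frag) + 1
        lines.append(f"{frag} = {_compress_ranges(idx)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _compress_ranges(indices: np.ndarray) -> str:
    parts = []
    run_start = prev = int(indices[0])
    for i in list(indices[1:]) + [None]:
        if i is not None and int(i) == prev + 1:
            prev = int(i)
            continue
        parts.append(str(run_start) if run_start == prev else f"{run_start}-{prev}")
        if i is not None:
            run_start = prev = int(i)
    return ",".join(parts)


def read_xyz(path: str | Path, fragment_config: str | Path | None = None) -> Molecule:
    """Read a standard XYZ file.

    The comment line may carry an optional fragment tag of the form
    ``frags=A:1-6;B:7-12`` (1-based inclusive ranges). A sidecar
    ``fragment_config`` file wins over the comment-line tag on conflict,
    with a logged warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n_declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}:1: expected atom count, got {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) != n_declared:
        raise XYZParseError(
            f"{path}: header declares {n_declared} atoms but found "
            f"{len(records)} coordinate records (first record is line 3)"
        )
    atoms = []
    for offset, rec in enumerate(records):
        fields = rec.split()
        if len(fields) < 4:
            raise XYZParseError(f"{path}:{offset + 3}: expected 'El x y z', got {rec!r}")
        el = fields[0]
        if el not in ATOMIC_NUMBERS:
            raise XYZParseError(
                f"{path}:{offset + 3}: unknown element {el!r}; supported: "
                f"{sorted(ATOMIC_NUMBERS)}"
            )
        try:
            xyz = [float(v) for v in fields[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}:{offset + 3}: bad coordinates in {rec!r}") from None
        atoms.append(Atom(el, np.array(xyz)))

    labels: list[str] | None = None
    m = _FRAG_COMMENT.search(comment)
    if m:
        spec_pairs = []
        for chunk in m.group(1).split(";"):
            if ":" not in chunk:
                raise XYZParseError(f"{path}:2: bad fragment chunk {chunk!r}")
            name, spec = chunk.split(":", 1)
            spec_pairs.append((name, spec))
        labels = _labels_from_spec(spec_pairs, len(atoms), f"{path}:2")
    if fragment_config is not None:
        config_labels = read_fragment_config(fragment_config, len(atoms))
        if labels is not None and config_labels != labels:
            logger.warning(
                "%s: fragment config %s overrides conflicting comment-line tags",
                path, fragment_config,
            )
        labels = config_labels
    return Molecule(atoms=atoms, fragment_labels=labels or ["1"] * len(atoms))


def write_xyz(path: str | Path, molecule: Molecule, comment: str | None = None) -> None:
    """Write XYZ with 10-decimal fixed-width coordinates.

    Unless ``comment`` is given, the comment line carries the fragment tag
    so that ``read_xyz(write_xyz(m))`` round-trips fragment labels.
    """
    if comment is None:
        chunks = [
            f"{frag}:{_compress_ranges(molecule.fragment_indices(frag) + 1)}"
            for frag in molecule.fragments
        ]
        comment = "frags=" + ";".join(chunks)
    lines = [str(molecule.n_atoms), comment]
    for a in molecule.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Masses and centers of mass


def _selection_indices(molecule: Molecule, selection: str | None) -> np.ndarray:
    if selection is None:
        return np.arange(molecule.n_atoms)
    return molecule.fragment_indices(selection)


def molecular_mass(molecule: Molecule, selection: str | None = None) -> float:
    """Sum of standard atomic weights (amu) over the molecule or one fragment."""
    masses = atomic_masses()
    idx = _selection_indices(molecule, selection)
    return float(sum(masses[molecule.atoms[i].element] for i in idx))


def center_of_mass(molecule: Molecule, selection: str | None = None) -> np.ndarray:
    """Mass-weighted mean position (angstrom) of the molecule or one fragment."""
    masses = atomic_masses()
    idx = _selection_indices(molecule, selection)
    w = np.array([masses[molecule.atoms[i].element] for i in idx])
    pos = molecule.positions[idx]
    return (w[:, None] * pos).sum(axis=0) / w.sum()


def com_distance(molecule: Molecule, frag_a: str, frag_b: str) -> float:
    """Distance (angstrom) between the centers of mass of two disjoint fragments."""
    ia = set(molecule.fragment_indices(frag_a).tolist())
    ib = set(molecule.fragment_indices(frag_b).tolist())
    if ia & ib:
        raise ValueError(f"fragments {frag_a!r} and {frag_b!r} share atoms")
    return float(np.linalg.norm(center_of_mass(molecule, frag_a)
                                - center_of_mass(molecule, frag_b)))
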