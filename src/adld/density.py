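"""Dispersion density fields and Gaussian cube I/O.

The dispersion density smears atomic contributions onto a 3-D grid,

    rho_disp(r) = N(alpha) * sum_A eps_A * exp(-alpha * |r - R_A|^2),

so that spatial patterns of stabilization become visible in standard
volumetric viewers. With the default normalizing prefactor
N = (alpha/pi)^{3/2} each atomic term integrates analytically to eps_A and
the whole field to the total dispersion energy. A ``paper_prefactor`` flag
switches to the (pi*alpha)^{-3/2} variant seen in some prints, which
matches the normalizing form only at alpha = 1 and is provided solely to
reproduce figure scales.

alpha is in 1/angstrom^2 (coordinates are angstrom); typical values are
0.5 for single-structure maps and 0.3 for difference maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM
from .geometry import ATOMIC_NUMBERS, Atom, Molecule
from .partition import AtomicContributionSet, DeltaContributionSet

__all__ = [
    "ScalarField",
    "SmearingParams",
    "dispersion_density",
    "delta_density",
    "write_cube",
    "read_cube",
]

_MAX_POINTS = 512**3


@dataclass(frozen=True)
class SmearingParams:
    """Gaussian smearing and grid parameters.

    alpha : Gaussian exponent, 1/angstrom^2 (default 0.5; use ~0.3 for
            difference maps).
    spacing : grid step, angstrom.
    padding : margin added around the atomic bounding box, angstrom.
    """

    alpha: float = 0.5
    spacing: float = 0.2
    padding: float = 4.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.padding < 0:
            raise ValueError(f"padding must be non-negative, got {self.padding}")


@dataclass(frozen=True)
class ScalarField:
    """Axis-aligned uniform grid of scalar values (kcal/mol/angstrom^3).

    ``values[i, j, k]`` sits at ``origin + (i*dx, j*dy, k*dz)``.
    """

    origin: np.ndarray
    steps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        steps = np.asarray(self.steps, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if origin.shape != (3,) or steps.shape != (3,):
            raise ValueError("origin and steps must be 3-vectors")
        if np.any(steps <= 0):
            raise ValueError(f"grid steps must be positive, got {steps}")
        if values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("field contains non-finite values")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "values", values)

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.steps[d] * np.arange(self.values.shape[d])
            for d in range(3)
        )  # type: ignore[return-value]

    def integral(self) -> float:
        """Trapezoidal quadrature of the field over the grid, kcal/mol."""
        out = self.values
        for d in range(3):
            out = np.trapezoid(out, dx=self.steps[d], axis=0)
        return float(out)


def _superpose(positions: np.ndarray, weights: np.ndarray, p: SmearingParams,
               paper_prefactor: bool, max_points: int) -> ScalarField:
    lo = positions.min(axis=0) - p.padding
    hi = positions.max(axis=0) + p.padding
    counts = np.maximum(np.ceil((hi - lo) / p.spacing).astype(int) + 1, 2)
    if int(np.prod(counts)) > max_points:
        raise ValueError(
            f"grid of {counts} points exceeds the {max_points}-point guard; "
            "increase spacing, reduce padding, or raise max_points explicitly"
        )
    axes = [lo[d] + p.spacing * np.arange(counts[d]) for d in range(3)]
    if paper_prefactor:
        prefactor = (math.pi * p.alpha) ** -1.5
    else:
        prefactor = (p.alpha / math.pi) ** 1.5
    values = np.zeros(tuple(counts))
    for pos, w in zip(positions, weights):
        if w == 0.0:
            continue
        # separable Gaussian: outer product of three 1-D profiles
        gx = np.exp(-p.alpha * (axes[0] - pos[0]) ** 2)
        gy = np.exp(-p.alpha * (axes[1] - pos[1]) ** 2)
        gz = np.exp(-p.alpha * (axes[2] - pos[2]) ** 2)
        values += (w * prefactor) * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return ScalarField(origin=lo, steps=np.full(3, p.spacing), values=values)


def dispersion_density(molecule: Molecule, acs: AtomicContributionSet,
                       params: SmearingParams | None = None,
                       paper_prefactor: bool = False,
                       max_points: int = _MAX_POINTS) -> ScalarField:
    """Gaussian-smeared dispersion density of an atomic contribution set."""
    params = params or SmearingParams()
    if acs.molecule.n_atoms != molecule.n_atoms:
        raise ValueError("contribution set does not match the molecule")
    return _superpose(molecule.positions, acs.eps, params, paper_prefactor, max_points)


def delta_density(dcs: DeltaContributionSet,
                  params: SmearingParams | None = None,
                  paper_prefactor: bool = False,
                  max_points: int = _MAX_POINTS) -> ScalarField:
    """Difference density: Delta_eps weights smeared at the anchor coordinates."""
    params = params or SmearingParams(alpha=0.3)
    return _superpose(dcs.anchor.positions, dcs.delta_eps, params,
                      paper_prefactor, max_points)


# --------------------------------------------------------------------------
# Gaussian cube I/O (Bohr units, z-fastest value ordering)

_Z_TO_SYMBOL = {z: el for el, z in ATOMIC_NUMBERS.items()}


def write_cube(path: str | Path, field: ScalarField, molecule: Molecule,
               comment: str = "ADLD dispersion density") -> None:
    """Write a standard Gaussian cube file (lengths converted to bohr)."""
    nx, ny, nz = field.counts
    b = BOHR_PER_ANGSTROM
    lines = [comment, "values in kcal/mol/A^3 on a uniform grid (z fastest)"]
    ox, oy, oz = field.origin * b
    lines.append(f"{molecule.n_atoms:5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}")
    for count, step_a in zip((nx, ny, nz), np.diag(field.steps * b)):
        lines.append(f"{count:5d} {step_a[0]:12.6f} {step_a[1]:12.6f} {step_a[2]:12.6f}")
    for atom in molecule.atoms:
        x, y, z = atom.position * b
        lines.append(
            f"{atom.atomic_number:5d} {float(atom.atomic_number):12.6f} "
            f"{x:12.6f} {y:12.6f} {z:12.6f}"
        )
    flat = field.values.reshape(-1)  # C order: z fastest
    for start in range(0, flat.size, 6):
        lines.append(" ".join(f"{v:13.5E}" for v in flat[start:start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> tuple[ScalarField, Molecule]:
    """Read a Gaussian cube file back into angstrom units.

    Only axis-aligned orthogonal grids are supported.
    """
    tokens_lines = Path(path).read_text().splitlines()
    if len(tokens_lines) < 6:
        raise ValueError(f"{path}: truncated cube header")
    header = tokens_lines[2].split()
    n_atoms = int(header[0])
    if n_atoms < 0:
        raise ValueError(f"{path}: negative atom counts (unsupported cube dialect)")
    origin = np.array([float(v) for v in header[1:4]]) * ANGSTROM_PER_BOHR
    counts = []
    steps = []
    for d in range(3):
        fields = tokens_lines[3 + d].split()
        count = int(fields[0])
        if count <= 0:
            raise ValueError(f"{path}: non-positive grid count {count}")
        vec = np.array([float(v) for v in fields[1:4]])
        off_axis = np.delete(vec, d)
        if np.any(off_axis != 0.0):
            raise ValueError(f"{path}: non-axis-aligned grid axis {vec}")
        counts.append(count)
        steps.append(vec[d] * ANGSTROM_PER_BOHR)
    atoms = []
    for i in range(n_atoms):
        fields = tokens_lines[6 + i].split()
        z = int(fields[0])
        if z not in _Z_TO_SYMBOL:
            raise ValueError(f"{path}: unsupported atomic number {z}")
        pos = np.array([float(v) for v in fields[2:5]]) * ANGSTROM_PER_BOHR
        atoms.append(Atom(_Z_TO_SYMBOL[z], pos))
    values = np.array(
        [float(v) for line in tokens_lines[6 + n_atoms:] for v in line.split()]
    )
    expected = counts[0] * counts[1] * counts[2]
    if values.size != expected:
        raise ValueError(f"{path}: expected {expected} grid values, found {values.size}")
    field = ScalarField(origin=origin, steps=np.array(steps),
                        values=values.reshape(tuple(counts)))
    return field, Molecule(atoms=atoms)
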