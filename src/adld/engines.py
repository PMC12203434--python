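"""Pairwise London-dispersion engines.

Two engines share one surface:

* ``london`` — the classic London combination rule
  C6_AB = (3/2) * alpha_A*alpha_B * I_A*I_B/(I_A+I_B)
  built from packaged static polarizabilities and ionization energies
  (C6-only, Becke-Johnson damped).
* ``cnd`` — a coordination-number-dependent C6 model: homoatomic reference
  C6 values are Gaussian-interpolated in CN, combined geometrically across
  elements, augmented with a C8 = 3*C6*r4r2_A*r4r2_B term and BJ-damped.

A pluggable :class:`ChargeScaler` makes either engine sensitive to atomic
partial charges; without one, both engines are charge-blind by construction.
All engine-internal arithmetic is in Hartree atomic units; the API takes
angstrom and returns kcal/mol. Dispersion energies are negative
(stabilizing) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .constants import A3_TO_BOHR3, BOHR_PER_ANGSTROM, EV_TO_HARTREE, HARTREE_TO_KCALMOL
from .geometry import Molecule
from .params import CndC6Params, LondonParams, damping_preset, load_cnd_params, load_london_params

__all__ = [
    "PairEnergyMatrix",
    "ChargeScaler",
    "ExponentialChargeScaler",
    "coordination_number",
    "london_c6",
    "c6_interpolated",
    "pair_energy_bj",
    "total_dispersion",
    "charge_sweep",
    "ENGINES",
]

ENGINES = ("london", "cnd")


@dataclass(frozen=True)
class PairEnergyMatrix:
    """Symmetric matrix of atom-pair dispersion energies in kcal/mol.

    The total dispersion energy is the sum over distinct pairs, i.e. the sum
    of the strict upper triangle.
    """

    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError(f"pair matrix must be square, got shape {e.shape}")
        if not np.all(np.isfinite(e)):
            raise ValueError("pair matrix contains non-finite entries")
        if not np.array_equal(e, e.T):
            raise ValueError("pair matrix must be symmetric")
        if np.any(np.diagonal(e) != 0.0):
            raise ValueError("pair matrix diagonal must be zero")
        object.__setattr__(self, "energies", e)

    @property
    def n_atoms(self) -> int:
        return self.energies.shape[0]

    @property
    def total(self) -> float:
        """Sum over distinct pairs (strict upper triangle), kcal/mol."""
        iu = np.triu_indices(self.n_atoms, k=1)
        return float(self.energies[iu].sum())


@runtime_checkable
class ChargeScaler(Protocol):
    """Contract for charge sensitivity of C6 / polarizability inputs.

    Implementations must satisfy: ``scale(v, 0) == v`` exactly, strictly
    decreasing in ``q`` for ``q > 0``, and strictly positive output over the
    physical charge range.
    """

    def scale(self, base_value: float, q: float) -> float: ...


class ExponentialChargeScaler:
    """Single-parameter exponential charge damping: ``v * exp(-b*q)``.

    The default decay constant ``b`` is calibrated once against the packaged
    polarizability table so that ``alpha(Li) * exp(-b)`` reproduces the
    packaged alpha(Li+) at q = +1.
    """

    def __init__(self, b: float | None = None):
        if b is None:
            pol = load_london_params().polarizability
            b = math.log(pol["Li"] / pol["Li+"])
        if b <= 0:
            raise ValueError(f"decay constant must be positive, got {b}")
        self.b = float(b)

    def scale(self, base_value: float, q: float) -> float:
        if q == 0.0:
            return base_value
        return base_value * math.exp(-self.b * q)

    def __repr__(self) -> str:
        return f"ExponentialChargeScaler(b={self.b:.6f})"


def coordination_number(molecule: Molecule, params: CndC6Params | None = None) -> np.ndarray:
    """Smooth per-atom coordination numbers.

    CN_A = sum_{B != A} 1 / (1 + exp(-k1 * (k2*(Rcov_A + Rcov_B)/r_AB - 1)))
    with covalent radii in angstrom from the packaged table. Pairs beyond
    ``params.cn_cutoff`` contribute zero, which removes the ~1e-7 asymptotic
    saturation of the logistic count at large separations.
    """
    params = params or load_cnd_params()
    try:
        rcov = np.array([params.covalent_radius[el] for el in molecule.elements])
    except KeyError as exc:
        raise KeyError(
            f"no covalent radius for element {exc.args[0]!r}; supported: "
            f"{sorted(params.covalent_radius)}"
        ) from None
    pos = molecule.positions
    n = molecule.n_atoms
    cn = np.zeros(n)
    if n == 1:
        return cn
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(r, np.inf)
    rcov_sum = rcov[:, None] + rcov[None, :]
    arg = -params.k1 * (params.k2 * rcov_sum / r - 1.0)
    # clip keeps exp() finite for overlapping/huge separations
    count = 1.0 / (1.0 + np.exp(np.clip(arg, -50.0, 50.0)))
    count[r > params.cn_cutoff] = 0.0
    np.fill_diagonal(count, 0.0)
    return count.sum(axis=1)


def london_c6(pol_a: float, pol_b: float, ie_a: float, ie_b: float) -> float:
    """London-formula C6 in hartree*bohr^6.

    Inputs: polarizabilities in angstrom^3, ionization energies in eV.
    C6 = (3/2) * alpha_A*alpha_B * I_A*I_B / (I_A + I_B), all in a.u.
    """
    if min(ie_a, ie_b) <= 0 or min(pol_a, pol_b) < 0:
        raise ValueError("polarizabilities must be >= 0 and ionization energies > 0")
    a_au = pol_a * A3_TO_BOHR3
    b_au = pol_b * A3_TO_BOHR3
    ia_au = ie_a * EV_TO_HARTREE
    ib_au = ie_b * EV_TO_HARTREE
    return 1.5 * a_au * b_au * ia_au * ib_au / (ia_au + ib_au)


def c6_interpolated(elem_a: str, elem_b: str, cn_a: float, cn_b: float,
                    params: CndC6Params | None = None) -> float:
    """CN-interpolated pair C6 (hartree*bohr^6).

    Gaussian weights w_ij = exp(-k3*((CN_A - CN_i)^2 + (CN_B - CN_j)^2)) over
    the reference points of each element; the pair reference value is the
    geometric mean of the homoatomic references. Symmetric under swapping
    (A, cn_a) with (B, cn_b).
    """
    params = params or load_cnd_params()
    for el in (elem_a, elem_b):
        if el not in params.reference_points:
            raise KeyError(
                f"no C6 reference data for element {el!r}; supported: "
                f"{sorted(params.reference_points)}"
            )
    refs_a = params.reference_points[elem_a]
    refs_b = params.reference_points[elem_b]
    num = 0.0
    den = 0.0
    for cn_i, c6_i in refs_a:
        for cn_j, c6_j in refs_b:
            w = math.exp(-params.k3 * ((cn_a - cn_i) ** 2 + (cn_b - cn_j) ** 2))
            num += w * math.sqrt(c6_i * c6_j)
            den += w
    return num / den


def pair_energy_bj(c6: float, c8: float, r: float,
                   damping: tuple[float, float, float, float]) -> float:
    """Becke-Johnson damped pair energy, kcal/mol.

    E = -s6*C6/(r^6 + f0^6) - s8*C8/(r^8 + f0^8),  f0 = a1*sqrt(C8/C6) + a2.
    ``c6``/``c8`` in hartree*bohr^6 / hartree*bohr^8, ``r`` in angstrom,
    ``a2`` in bohr. Finite (and zero-slope) as r -> 0.
    """
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    if c6 == 0.0 and c8 == 0.0:
        return 0.0
    s6, s8, a1, a2 = damping
    r_au = r * BOHR_PER_ANGSTROM
    f0 = a1 * math.sqrt(c8 / c6) + a2 if c6 > 0 else a2
    e_h = -s6 * c6 / (r_au**6 + f0**6) - s8 * c8 / (r_au**8 + f0**8)
    return e_h * HARTREE_TO_KCALMOL


def _resolve_damping(damping: str | tuple[float, float, float, float]) -> tuple[float, float, float, float]:
    if isinstance(damping, str):
        return damping_preset(damping)
    s6, s8, a1, a2 = damping
    return (float(s6), float(s8), float(a1), float(a2))


def _pair_c6_c8_london(molecule: Molecule, charges: np.ndarray | None,
                       scaler: ChargeScaler | None,
                       params: LondonParams) -> tuple[np.ndarray, np.ndarray]:
    pol, ie = [], []
    for i, el in enumerate(molecule.elements):
        if el not in params.polarizability:
            raise KeyError(
                f"element {el!r} not in the London parameter table; supported: "
                f"{sorted(params.polarizability)}"
            )
        a = params.polarizability[el]
        if scaler is not None and charges is not None:
            a = scaler.scale(a, float(charges[i]))
        pol.append(a)
        ie.append(params.ionization_energy[el])
    n = molecule.n_atoms
    c6 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c6[i, j] = c6[j, i] = london_c6(pol[i], pol[j], ie[i], ie[j])
    return c6, np.zeros((n, n))


def _pair_c6_c8_cnd(molecule: Molecule, charges: np.ndarray | None,
                    scaler: ChargeScaler | None,
                    params: CndC6Params) -> tuple[np.ndarray, np.ndarray]:
    cn = coordination_number(molecule, params)
    elements = molecule.elements
    for el in elements:
        if el not in params.reference_points:
            raise KeyError(
                f"element {el!r} not in the C6 reference table; supported: "
                f"{sorted(params.reference_points)}"
            )
    n = molecule.n_atoms
    c6 = np.zeros((n, n))
    c8 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = c6_interpolated(elements[i], elements[j], cn[i], cn[j], params)
            if scaler is not None and charges is not None:
                # per-atom geometric factors keep the scaled pair C6 symmetric
                v = math.sqrt(scaler.scale(v, float(charges[i]))
                              * scaler.scale(v, float(charges[j])))
            c6[i, j] = c6[j, i] = v
            w = 3.0 * v * params.r4r2[elements[i]] * params.r4r2[elements[j]]
            c8[i, j] = c8[j, i] = w
    return c6, c8


def total_dispersion(
    molecule: Molecule,
    engine: str = "cnd",
    charges: Sequence[float] | None = None,
    scaler: ChargeScaler | None = None,
    damping: str | tuple[float, float, float, float] = "PBE0",
    cutoff: float | None = None,
) -> tuple[PairEnergyMatrix, float]:
    """Pairwise dispersion energy of a molecule.

    Parameters
    ----------
    molecule
        Geometry (angstrom). Unsupported elements raise ``KeyError``.
    engine
        ``"london"`` or ``"cnd"``.
    charges
        Optional per-atom partial charges (e). Only used when a ``scaler``
        is supplied; without a scaler the engines are charge-blind.
    scaler
        A :class:`ChargeScaler`. ``None`` disables charge sensitivity.
    damping
        BJ preset name (``PBE0``, ``B3LYP``) or an explicit (s6, s8, a1, a2).
    cutoff
        Optional pair-distance cutoff in angstrom (pairs beyond it contribute
        zero); ``None`` (default) includes all pairs.

    Returns
    -------
    (PairEnergyMatrix, total)
        Pair energies and their sum over distinct pairs, kcal/mol.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    q = None
    if charges is not None:
        q = np.asarray(charges, dtype=float)
        if q.shape != (molecule.n_atoms,):
            raise ValueError(
                f"expected {molecule.n_atoms} charges, got shape {q.shape}"
            )
    damp = _resolve_damping(damping)
    if engine == "london":
        c6, c8 = _pair_c6_c8_london(molecule, q, scaler, load_london_params())
    else:
        c6, c8 = _pair_c6_c8_cnd(molecule, q, scaler, load_cnd_params())
    pos = molecule.positions
    n = molecule.n_atoms
    e = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(pos[i] - pos[j]))
            if cutoff is not None and r > cutoff:
                continue
            e[i, j] = e[j, i] = pair_energy_bj(c6[i, j], c8[i, j], r, damp)
    pairs = PairEnergyMatrix(e)
    return pairs, pairs.total


def charge_sweep(
    molecule: Molecule,
    atom: int,
    q_grid: Sequence[float],
    engine: str = "cnd",
    scaler: ChargeScaler | None = None,
    damping: str | tuple[float, float, float, float] = "PBE0",
):
    """Atomic dispersion contribution of one atom as a function of its charge.

    For each q in ``q_grid`` the chosen atom carries partial charge q (all
    others neutral) and the full decomposition is recomputed. Returns a list
    of ``(q, AtomicContributionSet)`` pairs; the atom's curve is
    ``[(q, acs.eps[atom]) for q, acs in result]``.
    """
    from .partition import atomic_contributions  # deferred: partition builds on engines

    if not 0 <= atom < molecule.n_atoms:
        raise IndexError(f"atom index {atom} out of range 0..{molecule.n_atoms - 1}")
    if scaler is None:
        scaler = ExponentialChargeScaler()
    out = []
    for q in q_grid:
        charges = np.zeros(molecule.n_atoms)
        charges[atom] = q
        pairs, _total = total_dispersion(
            molecule, engine=engine, charges=charges, scaler=scaler, damping=damping
        )
        acs = atomic_contributions(pairs, molecule=molecule,
                                   provenance=f"{engine}[q({atom})={q:g}]")
        out.append((float(q), acs))
    return out
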