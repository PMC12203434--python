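"""Mass-scaling analysis of dispersion energies over dimer sets.

Total pairwise dispersion energies of molecular dimers have been observed
to correlate with M1*M2/R — a "gravitational-like" relationship. Because
intramolecular dispersion usually dominates and, for compact monomers,
E1 ~ M1^2 (atomic polarizability tracks atomic mass), the deeper law is

    E_tot = beta * (M1^2 + M2^2) + gamma,

with gamma absorbing the average intermolecular contribution. For
equal-mass dimers M1^2 + M2^2 = 2*M1*M2, so the two laws coincide; for
mass-asymmetric dimers only the generalized form survives. This module
builds dimer records from geometries and fits both laws plus the
diagnostic regressions (intramolecular vs M1*M2, interaction vs M1*M2/R,
total vs M1+M2 for the linear-scaling regime of large systems).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .engines import total_dispersion
from .geometry import Molecule, com_distance, molecular_mass
from .params import load_london_params
from .partition import supramolecular_split

logger = logging.getLogger(__name__)

__all__ = [
    "DimerRecord",
    "FitResult",
    "build_records",
    "fit_gravitational",
    "fit_generalized",
    "fit_intramolecular",
    "fit_interaction",
    "fit_mass_sum",
    "compact_cluster_check",
]


@dataclass(frozen=True)
class DimerRecord:
    """One dimer's dispersion decomposition and mass/separation descriptors.

    Energies in kcal/mol; masses in amu; R (center-of-mass separation) in
    angstrom. E_tot = E1 + E2 + E_int.
    """

    label: str
    e_tot: float
    e1: float
    e2: float
    e_int: float
    m1: float
    m2: float
    r: float

    def __post_init__(self) -> None:
        if self.m1 <= 0 or self.m2 <= 0 or self.r <= 0:
            raise ValueError(f"{self.label}: masses and R must be positive")
        scale = max(1.0, abs(self.e_tot))
        if abs(self.e_tot - (self.e1 + self.e2 + self.e_int)) > 1e-8 * scale:
            raise ValueError(
                f"{self.label}: E_tot != E1 + E2 + E_int beyond 1e-8 relative"
            )


@dataclass(frozen=True)
class FitResult:
    """Ordinary least squares summary for one predictor."""

    predictor: str
    slope: float
    intercept: float
    r2: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 or math.isnan(self.r2)):
            raise ValueError(f"R^2 out of [0, 1]: {self.r2}")


def build_records(
    dimers: list[tuple[Molecule, str, str]] | list[tuple[str, Molecule, str, str]],
    engine: str = "cnd",
    convention: str = "isolated-monomer",
    damping="PBE0",
) -> list[DimerRecord]:
    """One :class:`DimerRecord` per (molecule, fragA, fragB) input.

    Inputs may carry an optional leading label; otherwise dimers are
    labelled ``dimer-<k>``.
    """
    records = []
    for k, item in enumerate(dimers, start=1):
        if len(item) == 4:
            label, mol, fa, fb = item  # type: ignore[misc]
        else:
            mol, fa, fb = item  # type: ignore[misc]
            label = f"dimer-{k}"
        split = supramolecular_split(mol, fa, fb, engine=engine,
                                     convention=convention, damping=damping)
        records.append(DimerRecord(
            label=label,
            e_tot=split.e_tot, e1=split.e1, e2=split.e2, e_int=split.e_int,
            m1=molecular_mass(mol, fa), m2=molecular_mass(mol, fb),
            r=com_distance(mol, fa, fb),
        ))
    return records


def _ols(x: np.ndarray, y: np.ndarray, predictor: str,
         intercept: bool = True) -> FitResult:
    if x.size < 3:
        raise ValueError(
            f"need at least 3 records to fit {predictor}, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise ValueError(
            f"degenerate predictor {predictor}: zero variance across records"
        )
    if intercept:
        design = np.column_stack([x, np.ones_like(x)])
    else:
        design = x[:, None]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope = float(coef[0])
    b = float(coef[1]) if intercept else 0.0
    fitted = slope * x + b
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        logger.warning("degenerate response for %s (zero variance); reporting R^2 = 0",
                       predictor)
        r2 = 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return FitResult(predictor=predictor, slope=slope, intercept=b,
                     r2=r2, residuals=resid)


def _arrays(records: list[DimerRecord]):
    get = lambda attr: np.array([getattr(r, attr) for r in records], dtype=float)
    return get("e_tot"), get("e1"), get("e2"), get("e_int"), get("m1"), get("m2"), get("r")


def fit_gravitational(records: list[DimerRecord], intercept: bool = True) -> FitResult:
    """E_tot ~ M1*M2/R (the gravitational-like law)."""
    e_tot, _, _, _, m1, m2, r = _arrays(records)
    return _ols(m1 * m2 / r, e_tot, "M1*M2/R", intercept)


def fit_generalized(records: list[DimerRecord], intercept: bool = True) -> FitResult:
    """E_tot ~ M1^2 + M2^2 (the generalized mass law; slope=beta, intercept=gamma)."""
    e_tot, _, _, _, m1, m2, _ = _arrays(records)
    return _ols(m1**2 + m2**2, e_tot, "M1^2+M2^2", intercept)


def fit_intramolecular(records: list[DimerRecord], intercept: bool = True) -> FitResult:
    """E1 + E2 ~ M1*M2 (intramolecular correlate)."""
    _, e1, e2, _, m1, m2, _ = _arrays(records)
    return _ols(m1 * m2, e1 + e2, "M1*M2", intercept)


def fit_interaction(records: list[DimerRecord], intercept: bool = True) -> FitResult:
    """E_int ~ M1*M2/R — a diagnostic expected NOT to correlate."""
    _, _, _, e_int, m1, m2, r = _arrays(records)
    return _ols(m1 * m2 / r, e_int, "M1*M2/R (interaction)", intercept)


def fit_mass_sum(records: list[DimerRecord], intercept: bool = True) -> FitResult:
    """E_tot ~ M1 + M2 (linear-scaling regime of extended systems)."""
    e_tot, _, _, _, m1, m2, _ = _arrays(records)
    return _ols(m1 + m2, e_tot, "M1+M2", intercept)


@dataclass(frozen=True)
class CompactClusterReport:
    """E1 / (sum_A alpha_A)^2 across a family of compact clusters.

    A near-constant ratio is the quantitative content of E1 ~ M1^2 for
    compact systems whose interatomic distances vary within a narrow range.
    ``relative_spread`` is (max - min) / |mean| of the ratios.
    """

    sizes: list[int]
    ratios: list[float]

    @property
    def relative_spread(self) -> float:
        arr = np.array(self.ratios)
        return float(np.ptp(arr) / abs(arr.mean()))


def compact_cluster_check(monomer_family: list[Molecule],
                          engine: str = "london",
                          damping="PBE0") -> CompactClusterReport:
    """Quantify E1 ~ (sum of polarizabilities)^2 over a cluster family."""
    pol = load_london_params().polarizability
    sizes, ratios = [], []
    for mol in monomer_family:
        _, e1 = total_dispersion(mol, engine=engine, damping=damping)
        alpha_sum = sum(pol[el] for el in mol.elements)
        sizes.append(mol.n_atoms)
        ratios.append(0.0 if mol.n_atoms < 2 else e1 / alpha_sum**2)
    return CompactClusterReport(sizes=sizes, ratios=ratios)
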