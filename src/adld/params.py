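"""Packaged parameter tables and their loaders.

All numerical parameters live in documented CSV files under ``adld/data``
(element, value, source per row) so users can inspect or extend coverage
without touching code. Loaders cache the parsed tables per process.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "LondonParams",
    "CndC6Params",
    "atomic_masses",
    "load_london_params",
    "load_cnd_params",
    "damping_preset",
]


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("adld.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


@functools.lru_cache(maxsize=None)
def atomic_masses() -> dict[str, float]:
    """Standard atomic weights (amu) keyed by element symbol."""
    df = _read_table("masses.csv")
    return dict(zip(df["element"], df["mass_amu"].astype(float)))


@dataclass(frozen=True)
class LondonParams:
    """Per-species static polarizabilities (A^3) and ionization energies (eV).

    Species keys are element symbols, plus ion labels such as ``Li+`` so the
    charge-scaling layer can be calibrated against a real ionic reference.
    """

    polarizability: dict[str, float]
    ionization_energy: dict[str, float]

    def __post_init__(self) -> None:
        for table, label in ((self.polarizability, "polarizability"),
                             (self.ionization_energy, "ionization energy")):
            bad = [k for k, v in table.items() if not v > 0]
            if bad:
                raise ValueError(f"non-positive {label} for {bad}")
        for required in ("Li", "Li+"):
            if required not in self.polarizability:
                raise ValueError(f"species {required!r} missing from polarizability table")


@dataclass(frozen=True)
class CndC6Params:
    """Parameters of the coordination-number-interpolated C6 engine.

    ``reference_points`` maps an element to its (reference CN, homoatomic C6)
    list with C6 in hartree*bohr^6. ``r4r2`` enters the C8 recursion
    C8 = 3*C6*r4r2_A*r4r2_B; ``covalent_radius`` (angstrom) feeds the CN
    counting function with steepness constants ``k1``/``k2`` and Gaussian
    interpolation width ``k3``.
    """

    reference_points: dict[str, list[tuple[float, float]]]
    r4r2: dict[str, float]
    covalent_radius: dict[str, float]
    k1: float = 16.0
    k2: float = 4.0 / 3.0
    k3: float = 4.0
    cn_cutoff: float = 21.16709322  # angstrom (40 bohr); beyond it f_count = 0
    damping: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for elem, pts in self.reference_points.items():
            if not pts:
                raise ValueError(f"element {elem} has no C6 reference points")
            if any(c6 < 0 for _, c6 in pts):
                raise ValueError(f"negative reference C6 for {elem}")

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self.reference_points)


@functools.lru_cache(maxsize=None)
def load_london_params() -> LondonParams:
    df = _read_table("london_params.csv")
    return LondonParams(
        polarizability=dict(zip(df["species"], df["polarizability_A3"].astype(float))),
        ionization_energy=dict(zip(df["species"], df["ionization_eV"].astype(float))),
    )


@functools.lru_cache(maxsize=None)
def load_cnd_params() -> CndC6Params:
    refs = _read_table("cn_c6_reference.csv")
    aux = _read_table("cn_engine_params.csv")
    consts = dict(zip(_read_table("counting_function.csv")["constant"],
                      _read_table("counting_function.csv")["value"].astype(float)))
    damping_df = _read_table("damping_presets.csv")
    reference_points: dict[str, list[tuple[float, float]]] = {}
    for row in refs.itertuples(index=False):
        reference_points.setdefault(row.element, []).append(
            (float(row.cn_ref), float(row.c6_ref_au))
        )
    return CndC6Params(
        reference_points=reference_points,
        r4r2=dict(zip(aux["element"], aux["r4r2"].astype(float))),
        covalent_radius=dict(zip(aux["element"], aux["covalent_radius_A"].astype(float))),
        k1=consts["k1"],
        k2=consts["k2"],
        k3=consts["k3"],
        cn_cutoff=consts["cn_cutoff"],
        damping={row.preset: (float(row.s6), float(row.s8), float(row.a1), float(row.a2))
                 for row in damping_df.itertuples(index=False)},
    )


def damping_preset(name: str) -> tuple[float, float, float, float]:
    """Return (s6, s8, a1, a2) for a named functional preset (e.g. ``PBE0``)."""
    presets = load_cnd_params().damping
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown damping preset {name!r}; available: {sorted(presets)}"
        ) from None
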