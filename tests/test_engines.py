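import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adld.constants import BOHR_PER_ANGSTROM, EV_TO_HARTREE, HARTREE_TO_KCALMOL
from adld.engines import (
    ExponentialChargeScaler,
    PairEnergyMatrix,
    c6_interpolated,
    charge_sweep,
    coordination_number,
    london_c6,
    pair_energy_bj,
    total_dispersion,
)
from adld.geometry import Atom, Molecule
from adld.params import damping_preset, load_cnd_params, load_london_params
from conftest import random_rotation


def diatomic(el: str, r: float) -> Molecule:
    return Molecule([Atom(el, np.zeros(3)), Atom(el, np.array([0.0, 0.0, r]))])


# --------------------------------------------------------------------------
# coordination number


def test_cn_isolated_atom_is_zero():
    mol = Molecule([Atom("C", np.zeros(3))])
    assert coordination_number(mol).tolist() == [0.0]


def test_cn_vanishes_at_huge_separation():
    cn = coordination_number(diatomic("C", 100.0))
    assert np.all(cn < 1e-6)


def test_cn_h2_matches_direct_counting_function():
    params = load_cnd_params()
    r = 0.74
    rcov = 2 * params.covalent_radius["H"]
    expected = 1.0 / (1.0 + math.exp(-params.k1 * (params.k2 * rcov / r - 1.0)))
    cn = coordination_number(diatomic("H", r))
    np.testing.assert_allclose(cn, [expected, expected], rtol=1e-12)


def test_cn_unsupported_element():
    with pytest.raises(KeyError, match="covalent radius"):
        coordination_number(Molecule([Atom("Na", np.zeros(3))]))


# --------------------------------------------------------------------------
# C6 models


def test_london_c6_identical_atoms_closed_form():
    # identical species: C6 = (3/4) * alpha^2 * I  (in a.u.)
    alpha, ie = 1.5, 12.0
    a_au = alpha * BOHR_PER_ANGSTROM**3
    i_au = ie * EV_TO_HARTREE
    assert london_c6(alpha, alpha, ie, ie) == pytest.approx(0.75 * a_au**2 * i_au,
                                                            rel=1e-14)


def test_london_c6_zero_polarizability():
    assert london_c6(0.0, 1.0, 10.0, 10.0) == 0.0


def test_london_c6_hh_packaged_constants():
    p = load_london_params()
    a = p.polarizability["H"] * BOHR_PER_ANGSTROM**3
    i = p.ionization_energy["H"] * EV_TO_HARTREE
    expected = 1.5 * a * a * i * i / (i + i)
    assert london_c6(p.polarizability["H"], p.polarizability["H"],
                     p.ionization_energy["H"], p.ionization_energy["H"]) \
        == pytest.approx(expected, rel=1e-14)


def test_c6_interpolation_single_reference_point():
    params = load_cnd_params()
    (cn_ref, c6_ref), = params.reference_points["Ne"]
    for cn in (0.0, 0.7, 3.5):
        assert c6_interpolated("Ne", "Ne", cn, cn) == pytest.approx(c6_ref, rel=1e-12)


def test_c6_interpolation_at_reference_point():
    params = load_cnd_params()
    refs = params.reference_points["C"]
    cn0, c60 = refs[0]
    # brute-force weight evaluation at a reference CN
    num = den = 0.0
    for cni, c6i in refs:
        for cnj, c6j in refs:
            w = math.exp(-params.k3 * ((cn0 - cni) ** 2 + (cn0 - cnj) ** 2))
            num += w * math.sqrt(c6i * c6j)
            den += w
    assert c6_interpolated("C", "C", cn0, cn0) == pytest.approx(num / den, rel=1e-14)
    # references are ~1 CN apart, so the nearest dominates within a percent
    assert c6_interpolated("C", "C", cn0, cn0) == pytest.approx(c60, rel=0.05)


def test_c6_interpolation_swap_symmetry():
    assert c6_interpolated("C", "H", 2.3, 0.8) == pytest.approx(
        c6_interpolated("H", "C", 0.8, 2.3), rel=1e-14)


def test_c6_interpolation_unknown_element():
    with pytest.raises(KeyError, match="reference data"):
        c6_interpolated("C", "Na", 1.0, 1.0)


# --------------------------------------------------------------------------
# BJ-damped pair energy


def test_pair_energy_zero_coefficients():
    assert pair_energy_bj(0.0, 0.0, 3.0, damping_preset("PBE0")) == 0.0


def test_pair_energy_undamped_asymptote():
    damp = damping_preset("PBE0")
    s6, s8 = damp[0], damp[1]
    c6, c8 = 25.0, 500.0
    r = 40.0
    r_au = r * BOHR_PER_ANGSTROM
    # C6-only pair: damping is negligible at 40 A
    undamped_c6_only = -s6 * c6 / r_au**6 * HARTREE_TO_KCALMOL
    assert pair_energy_bj(c6, 0.0, r, damp) == pytest.approx(undamped_c6_only, rel=1e-3)
    # full form approaches its own undamped sum
    undamped_sum = (-s6 * c6 / r_au**6 - s8 * c8 / r_au**8) * HARTREE_TO_KCALMOL
    assert pair_energy_bj(c6, c8, r, damp) == pytest.approx(undamped_sum, rel=1e-3)


def test_pair_energy_hand_evaluation():
    s6, s8, a1, a2 = 1.0, 1.2177, 0.4145, 4.8593
    c6, c8 = 30.0, 900.0
    r_au = 3.0 * BOHR_PER_ANGSTROM
    f0 = a1 * math.sqrt(c8 / c6) + a2
    expected = (-s6 * c6 / (r_au**6 + f0**6)
                - s8 * c8 / (r_au**8 + f0**8)) * HARTREE_TO_KCALMOL
    assert pair_energy_bj(c6, c8, 3.0, (s6, s8, a1, a2)) == pytest.approx(expected,
                                                                          rel=1e-14)


def test_pair_energy_finite_at_short_range():
    val = pair_energy_bj(30.0, 900.0, 1e-6, damping_preset("PBE0"))
    assert np.isfinite(val) and val < 0


def test_pair_energy_requires_positive_distance():
    with pytest.raises(ValueError, match="positive"):
        pair_energy_bj(10.0, 100.0, 0.0, damping_preset("PBE0"))


# --------------------------------------------------------------------------
# total dispersion


def test_single_atom_no_pairs():
    for engine in ("london", "cnd"):
        pairs, total = total_dispersion(Molecule([Atom("C", np.zeros(3))]), engine=engine)
        assert total == 0.0
        assert pairs.energies.shape == (1, 1)


def test_diatomic_total_equals_single_pair():
    for engine in ("london", "cnd"):
        pairs, total = total_dispersion(diatomic("C", 1.5), engine=engine)
        assert total == pairs.energies[0, 1]
        assert total < 0


def test_total_equals_brute_force_double_loop(small_cluster):
    """O(N^2) oracle: rebuild every pair energy from the primitive operations."""
    params = load_cnd_params()
    damp = damping_preset("PBE0")
    cn = coordination_number(small_cluster)
    pos = small_cluster.positions
    els = small_cluster.elements
    expected = 0.0
    for i in range(small_cluster.n_atoms):
        for j in range(i + 1, small_cluster.n_atoms):
            c6 = c6_interpolated(els[i], els[j], cn[i], cn[j], params)
            c8 = 3.0 * c6 * params.r4r2[els[i]] * params.r4r2[els[j]]
            r = float(np.linalg.norm(pos[i] - pos[j]))
            expected += pair_energy_bj(c6, c8, r, damp)
    _, total = total_dispersion(small_cluster, engine="cnd")
    assert total == pytest.approx(expected, rel=1e-12)


def test_total_matches_pair_matrix_upper_triangle(small_cluster):
    for engine in ("london", "cnd"):
        pairs, total = total_dispersion(small_cluster, engine=engine)
        iu = np.triu_indices(pairs.n_atoms, k=1)
        assert total == float(pairs.energies[iu].sum())


def test_rigid_transform_invariance(small_cluster, rng):
    for engine in ("london", "cnd"):
        _, ref = total_dispersion(small_cluster, engine=engine)
        for _ in range(3):
            moved = small_cluster.transformed(rotation=random_rotation(rng),
                                              translation=rng.normal(size=3, scale=20))
            _, tot = total_dispersion(moved, engine=engine)
            assert tot == pytest.approx(ref, abs=1e-10)


def test_r6_decay_rare_gas_pair():
    _, e_r = total_dispersion(diatomic("Ne", 20.0), engine="london")
    _, e_2r = total_dispersion(diatomic("Ne", 40.0), engine="london")
    assert e_2r / e_r == pytest.approx(2.0**-6, rel=1e-3)


def test_unsupported_element_and_bad_charges(small_cluster):
    with pytest.raises(KeyError):
        total_dispersion(Molecule([Atom("Na", np.zeros(3)),
                                   Atom("Na", np.array([0, 0, 2.0]))]), engine="cnd")
    with pytest.raises(ValueError, match="charges"):
        total_dispersion(small_cluster, charges=[0.0, 0.0])


def test_pair_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        PairEnergyMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        PairEnergyMatrix(np.array([[1.0, 2.0], [2.0, 0.0]]))


# --------------------------------------------------------------------------
# charge scaling


def test_scaler_identity_at_zero_charge_bitwise(li_ring_complex):
    scaler = ExponentialChargeScaler()
    assert scaler.scale(3.7, 0.0) == 3.7
    q0 = np.zeros(li_ring_complex.n_atoms)
    for engine in ("london", "cnd"):
        _, plain = total_dispersion(li_ring_complex, engine=engine)
        _, scaled = total_dispersion(li_ring_complex, engine=engine,
                                     charges=q0, scaler=scaler)
        assert plain == scaled  # bitwise


def test_scaler_calibrated_to_packaged_li_cation():
    pol = load_london_params().polarizability
    scaler = ExponentialChargeScaler()
    assert scaler.scale(pol["Li"], 1.0) == pytest.approx(pol["Li+"], rel=1e-12)


@given(st.floats(0.01, 2.0), st.floats(0.01, 2.0))
@settings(max_examples=50, deadline=None)
def test_scaler_contract_monotone_positive(q1, q2):
    scaler = ExponentialChargeScaler()
    lo, hi = sorted((q1, q2))
    v_lo, v_hi = scaler.scale(5.0, lo), scaler.scale(5.0, hi)
    assert v_lo > 0 and v_hi > 0
    if hi > lo:
        assert v_hi < v_lo


def test_engine_without_scaler_is_charge_blind(li_ring_complex):
    charges = np.zeros(li_ring_complex.n_atoms)
    charges[-1] = 1.0
    for engine in ("london", "cnd"):
        _, plain = total_dispersion(li_ring_complex, engine=engine)
        _, charged = total_dispersion(li_ring_complex, engine=engine, charges=charges)
        assert plain == charged


def test_charge_sweep_monotone_and_pointwise(li_ring_complex):
    idx = li_ring_complex.elements.index("Li")
    grid = [0.0, 0.5, 1.0]
    for engine in ("london", "cnd"):
        result = charge_sweep(li_ring_complex, idx, grid, engine=engine)
        eps = [acs.eps[idx] for _, acs in result]
        # q = 0 equals the uncharged decomposition exactly
        from adld.partition import atomic_contributions
        pairs0, _ = total_dispersion(li_ring_complex, engine=engine)
        assert eps[0] == atomic_contributions(pairs0, li_ring_complex).eps[idx]
        # strictly decreasing magnitude with increasing positive charge
        mags = [abs(e) for e in eps]
        assert mags[0] > mags[1] > mags[2]
        # pointwise oracle: direct recomputation at each q
        for q, acs in result:
            charges = np.zeros(li_ring_complex.n_atoms)
            charges[idx] = q
            pairs, _ = total_dispersion(li_ring_complex, engine=engine,
                                        charges=charges,
                                        scaler=ExponentialChargeScaler())
            direct = atomic_contributions(pairs, li_ring_complex)
            assert acs.eps[idx] == pytest.approx(direct.eps[idx], rel=1e-14)


def test_charge_sweep_single_point_and_bad_index(li_ring_complex):
    result = charge_sweep(li_ring_complex, 0, [0.3])
    assert len(result) == 1
    with pytest.raises(IndexError):
        charge_sweep(li_ring_complex, 99, [0.0])
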