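"""Constitutive-model tests: energy values, stress consistency, invariance."""

import numpy as np
import pytest

from plaquefatigue.material import (
    TISSUE_PARAMS,
    DeformationState,
    MaterialParams,
    cauchy_stress,
    material_table,
    principal_values,
    strain_energy,
)

TISSUES = list(TISSUE_PARAMS)


def random_state(rng, max_pert=0.15):
    """Random admissible deformation state (J > 0, moderate strain)."""
    while True:
        F = np.eye(2) + max_pert * rng.standard_normal((2, 2))
        lz = 1.0 + 0.08 * rng.standard_normal()
        if np.linalg.det(F) * lz > 0.3:
            break
    th = rng.uniform(0.0, 2.0 * np.pi)
    return DeformationState(F, lz, np.array([np.cos(th), np.sin(th)]))


@pytest.mark.parametrize("tissue", TISSUES)
def test_reference_is_energy_and_stress_free(tissue):
    st = DeformationState(np.eye(2), 1.0)
    params = TISSUE_PARAMS[tissue]
    assert strain_energy(st, params) == pytest.approx(0.0, abs=1e-12)
    assert np.abs(cauchy_stress(st, params)).max() == pytest.approx(0.0, abs=1e-10)


def test_lipid_energy_matches_direct_formula_on_isochoric_uniaxial():
    # isochoric in-plane uniaxial stretch: the modified invariants equal the
    # plain ones, so the energy is the textbook expression evaluated directly
    lam = 1.2
    F = np.diag([lam, 1.0 / lam])
    st = DeformationState(F, 1.0)
    I1 = lam**2 + 1.0 / lam**2 + 1.0
    p = TISSUE_PARAMS["lipid"]
    C = np.diag([lam**2, 1.0 / lam**2, 1.0])
    I2 = 0.5 * (I1**2 - np.sum(C * C))
    expected = p.c1 * (I1 - 3) + p.c2 * (I2 - 3) + p.D1 * (np.exp(p.D2 * (I1 - 3)) - 1)
    assert strain_energy(st, p) == pytest.approx(expected, rel=1e-12)


def test_anisotropic_term_vanishes_when_fiber_is_unstretched():
    # stretch orthogonal to the fiber: I4 = 1, so wall energy equals the
    # isotropic part alone
    lam = 1.1
    F = np.diag([lam, 1.0])  # fiber along y
    st = DeformationState(F, 1.0, np.array([0.0, 1.0]))
    wall = TISSUE_PARAMS["wall"]
    iso_only = MaterialParams(c1=wall.c1, c2=wall.c2, D1=wall.D1, D2=wall.D2)
    assert st.I4 == pytest.approx(1.0, abs=1e-14)
    assert strain_energy(st, wall) == pytest.approx(strain_energy(st, iso_only), rel=1e-12)


@pytest.mark.parametrize("tissue", TISSUES)
def test_analytic_stress_matches_finite_difference_gradient(tissue):
    """sigma from analytic dW/dC agrees with central FD of W to 1e-5 relative."""
    rng = np.random.default_rng(42)
    params = TISSUE_PARAMS[tissue]
    h = 1e-6
    for _ in range(100):
        st = random_state(rng)
        sig = cauchy_stress(st, params)
        # compare via the first Piola stress P = J sigma F^-T
        P = st.J * sig[:2, :2] @ np.linalg.inv(st.F).T
        P_fd = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                Fp, Fm = st.F.copy(), st.F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                P_fd[i, j] = (
                    strain_energy(DeformationState(Fp, st.lambda_z, st.fiber), params)
                    - strain_energy(DeformationState(Fm, st.lambda_z, st.fiber), params)
                ) / (2 * h)
        scale = max(np.abs(P_fd).max(), 1e-8)
        assert np.abs(P - P_fd).max() / scale < 1e-5


@pytest.mark.parametrize("tissue", TISSUES)
def test_material_frame_indifference(tissue):
    """W(QF) = W(F) for rotations Q; fibers live in the reference frame."""
    rng = np.random.default_rng(3)
    params = TISSUE_PARAMS[tissue]
    for _ in range(20):
        st = random_state(rng)
        th = rng.uniform(0.0, 2.0 * np.pi)
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = DeformationState(Q @ st.F, st.lambda_z, st.fiber)
        assert strain_energy(rotated, params) == pytest.approx(
            strain_energy(st, params), rel=1e-12, abs=1e-12
        )


def test_incompressible_uniaxial_matches_mooney_rivlin_closed_form():
    """Penalty solution approximates the incompressible MR uniaxial stress.

    For an incompressible Mooney-Rivlin solid in uniaxial tension (stretch
    lam along the loaded axis, lateral stretches 1/sqrt(lam)), the axial
    minus lateral Cauchy stress is 2 (lam^2 - 1/lam) (W1 + W2 / lam).  On a
    kinematically prescribed isochoric state the hydrostatic part is
    indeterminate (set by boundary conditions, not the material), so the
    closed form is checked on the stress difference.
    """
    p = MaterialParams(c1=10.0, c2=5.0, D1=0.0, D2=1.0, kappa_vol=1e6)
    lam = 1.15
    # in-plane axial stretch lam (x), lateral 1/sqrt(lam) in y and z
    F = np.diag([lam, lam**-0.5])
    st = DeformationState(F, lam**-0.5)
    sig = cauchy_stress(st, p)
    expected = 2.0 * (lam**2 - 1.0 / lam) * (p.c1 + p.c2 / lam)
    assert sig[0, 0] - sig[1, 1] == pytest.approx(expected, rel=1e-9)
    # lateral directions are equivalent
    assert sig[1, 1] == pytest.approx(sig[2, 2], rel=1e-9)


def test_inverted_state_rejected():
    with pytest.raises(ValueError, match="inverted"):
        DeformationState(np.diag([-1.0, 1.0]), 1.0)


@pytest.mark.parametrize(
    "tensor, expected",
    [
        (np.diag([3.0, 1.0]), (3.0, 1.0)),
        (np.array([[0.0, 1.0], [1.0, 0.0]]), (1.0, -1.0)),
    ],
)
def test_principal_values_examples(tensor, expected):
    assert principal_values(tensor) == pytest.approx(expected)


def test_principal_values_match_characteristic_polynomial():
    rng = np.random.default_rng(5)
    for _ in range(50):
        a, b, c = rng.standard_normal(3)
        T = np.array([[a, c], [c, b]])
        mean, rad = 0.5 * (a + b), np.sqrt(0.25 * (a - b) ** 2 + c**2)
        assert principal_values(T) == pytest.approx((mean + rad, mean - rad))


def test_principal_values_reject_asymmetric():
    with pytest.raises(ValueError, match="symmetric"):
        principal_values(np.array([[1.0, 0.5], [0.0, 1.0]]))


def test_material_table_overrides():
    table = material_table({"lipid": {"c1": 2.0}})
    assert table["lipid"].c1 == 2.0
    assert table["wall"] == TISSUE_PARAMS["wall"]
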