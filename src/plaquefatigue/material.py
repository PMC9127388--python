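"""Modified Mooney-Rivlin hyperelasticity for atherosclerotic vessel tissue.

The strain-energy density is, in the invariants of the right Cauchy-Green
tensor ``C = X^T X``,

    W_iso   = c1 (I1 - 3) + c2 (I2 - 3) + D1 [exp(D2 (I1 - 3)) - 1]
    W_aniso = W_iso + (K1/K2) [exp(K2 (I4 - 1)^2) - 1]

with ``I4 = C : (nc x nc)`` for the circumferential fiber direction ``nc``.
Lipid and calcification are isotropic; the remaining vessel tissue carries
the anisotropic augmentation.  Near-incompressibility is enforced by a
volumetric penalty ``kappa_vol (J - 1)^2`` (a standard displacement-based
treatment; the penalty modulus is far above the tissue shear scale).  The
isochoric part is evaluated on the modified invariants ``I1_bar =
J^(-2/3) I1`` and ``I2_bar = J^(-4/3) I2`` — the standard decoupled
realization of a nearly incompressible material, which coincides with the
plain form on volume-preserving deformations and makes the reference
configuration exactly stress-free.

Deformation is generalized plane strain: an in-plane 2x2 deformation
gradient plus a prescribed axial stretch ``lambda_z``, so the 3D ``C`` is
block-diagonal.  All stresses are Cauchy stresses in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialParams",
    "DeformationState",
    "TISSUE_PARAMS",
    "material_table",
    "strain_energy",
    "cauchy_stress",
    "principal_values",
]


@dataclass(frozen=True)
class MaterialParams:
    """Parameters of the modified Mooney-Rivlin model (kPa where dimensional)."""

    c1: float
    c2: float
    D1: float
    D2: float
    K1: float = 0.0
    K2: float = 1.0
    anisotropic: bool = False
    kappa_vol: float = 1.0e4
    fiber_direction: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.anisotropic and (self.K2 <= 0.0):
            raise ValueError("K2 must be positive for the anisotropic term")
        if self.kappa_vol <= 0.0:
            raise ValueError("volumetric penalty must be positive")
        n = np.hypot(*self.fiber_direction)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError("fiber_direction must be a unit vector")

    def scaled(self, factor: float) -> "MaterialParams":
        """Return a copy with all stiffness-like moduli multiplied by *factor*.

        Used for near-rigid limiting cases (e.g. shrinkage sanity checks).
        """
        return replace(
            self,
            c1=self.c1 * factor,
            c2=self.c2 * factor,
            D1=self.D1 * factor,
            K1=self.K1 * factor,
            kappa_vol=self.kappa_vol * factor,
        )


#: Literature parameter sets for the three VH-IVUS tissue classes.
TISSUE_PARAMS: dict[str, MaterialParams] = {
    "lipid": MaterialParams(c1=0.5, c2=0.0, D1=0.5, D2=1.5),
    "calcium": MaterialParams(c1=92.0, c2=0.0, D1=36.0, D2=2.0),
    "wall": MaterialParams(
        c1=-278.7, c2=24.35, D1=133.7, D2=2.0, K1=7.19, K2=23.5, anisotropic=True
    ),
}


def material_table(overrides: dict[str, dict] | None = None) -> dict[str, MaterialParams]:
    """Default tissue->parameter map, optionally overridden per tissue.

    ``overrides`` maps tissue names to keyword dicts, e.g.
    ``{"lipid": {"c1": 1.0}}``.
    """
    table = dict(TISSUE_PARAMS)
    for tissue, kw in (overrides or {}).items():
        table[tissue] = replace(table.get(tissue, TISSUE_PARAMS["wall"]), **kw)
    return table


@dataclass
class DeformationState:
    """In-plane deformation gradient plus prescribed axial stretch."""

    F: np.ndarray  # (2, 2) in-plane deformation gradient
    lambda_z: float = 1.0
    fiber: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.fiber = np.asarray(self.fiber, dtype=float)
        if self.F.shape != (2, 2):
            raise ValueError("F must be 2x2 (in-plane)")
        if self.J <= 0.0:
            raise ValueError(f"inverted state: J = {self.J:.3g} <= 0")

    @property
    def C(self) -> np.ndarray:
        """3x3 right Cauchy-Green tensor (block-diagonal)."""
        C2 = self.F.T @ self.F
        C = np.zeros((3, 3))
        C[:2, :2] = C2
        C[2, 2] = self.lambda_z**2
        return C

    @property
    def I1(self) -> float:
        return float(np.trace(self.C))

    @property
    def I2(self) -> float:
        C = self.C
        return 0.5 * (self.I1**2 - float(np.sum(C * C)))

    @property
    def I4(self) -> float:
        C2 = self.F.T @ self.F
        return float(self.fiber @ C2 @ self.fiber)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F)) * self.lambda_z


# ---------------------------------------------------------------------------
# Vectorized kernels (used both by the scalar API and the FE solver).
# Leading axes of F2 broadcast; material parameters broadcast likewise.


def _energy_vec(I1, I2, I4, J, c1, c2, D1, D2, K1, K2, aniso, kappa):
    """W from the *modified* invariants I1_bar = J^(-2/3) I1, I2_bar = J^(-4/3) I2."""
    I1b = J ** (-2.0 / 3.0) * I1
    I2b = J ** (-4.0 / 3.0) * I2
    W = c1 * (I1b - 3.0) + c2 * (I2b - 3.0) + D1 * np.expm1(D2 * (I1b - 3.0))
    Wan = np.where(K2 > 0, (K1 / np.where(K2 > 0, K2, 1.0)) * np.expm1(K2 * (I4 - 1.0) ** 2), 0.0)
    return W + np.where(aniso, Wan, 0.0) + kappa * (J - 1.0) ** 2


def _derivs_vec(I1, I4, J, c1, c2, D1, D2, K1, K2, aniso, kappa):
    """Partial derivatives of W wrt I1_bar, I2_bar, I4, J (at fixed others)."""
    I1b = J ** (-2.0 / 3.0) * I1
    W1 = c1 + D1 * D2 * np.exp(D2 * (I1b - 3.0))
    W2 = c2 * np.ones_like(I1)
    W4 = np.where(aniso, 2.0 * K1 * (I4 - 1.0) * np.exp(K2 * (I4 - 1.0) ** 2), 0.0)
    WJ = 2.0 * kappa * (J - 1.0)
    return W1, W2, W4, WJ


def pk2_inplane_vec(F2, lambda_z, fibers, c1, c2, D1, D2, K1, K2, aniso, kappa):
    """Second Piola-Kirchhoff stress, vectorized over leading axes.

    Returns ``(S2, S_zz, W)``: the in-plane 2x2 block of S, the axial
    component, and the energy density.  ``F2`` has shape (..., 2, 2),
    ``fibers`` (..., 2); parameter arrays broadcast against the leading axes.
    """
    F2 = np.asarray(F2, dtype=float)
    C2 = np.einsum("...ki,...kj->...ij", F2, F2)
    lz2 = lambda_z**2
    trC2 = np.trace(C2, axis1=-2, axis2=-1)
    I1 = trC2 + lz2
    CC = np.sum(C2 * C2, axis=(-2, -1)) + lz2**2
    I2 = 0.5 * (I1**2 - CC)
    I4 = np.einsum("...i,...ij,...j->...", fibers, C2, fibers)
    detF2 = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
    J = detF2 * lambda_z
    if np.any(J <= 0.0):
        raise FloatingPointError("inverted element: det F <= 0")

    W1, W2, W4, WJ = _derivs_vec(I1, I4, J, c1, c2, D1, D2, K1, K2, aniso, kappa)
    W = _energy_vec(I1, I2, I4, J, c1, c2, D1, D2, K1, K2, aniso, kappa)

    eye = np.broadcast_to(np.eye(2), C2.shape)
    # inv(C2) via the 2x2 adjugate; det C2 = detF2^2
    invC2 = np.empty_like(C2)
    invC2[..., 0, 0] = C2[..., 1, 1]
    invC2[..., 1, 1] = C2[..., 0, 0]
    invC2[..., 0, 1] = -C2[..., 0, 1]
    invC2[..., 1, 0] = -C2[..., 1, 0]
    invC2 = invC2 / (detF2**2)[..., None, None]

    nn = fibers[..., :, None] * fibers[..., None, :]
    Jm23 = J ** (-2.0 / 3.0)
    Jm43 = J ** (-4.0 / 3.0)
    # S = 2 dW/dC with the isochoric-volumetric split:
    #   dI1_bar/dC = J^(-2/3) (I - I1/3 C^-1)
    #   dI2_bar/dC = J^(-4/3) (I1 I - C - 2 I2/3 C^-1)
    coef_inv = (
        -2.0 * W1 * Jm23 * I1 / 3.0
        - 2.0 * W2 * Jm43 * 2.0 * I2 / 3.0
        + WJ * J
    )
    S2 = (
        (2.0 * W1 * Jm23 + 2.0 * W2 * Jm43 * I1)[..., None, None] * eye
        - (2.0 * W2 * Jm43)[..., None, None] * C2
        + 2.0 * W4[..., None, None] * nn
        + coef_inv[..., None, None] * invC2
    )
    S_zz = (
        2.0 * W1 * Jm23
        + 2.0 * W2 * Jm43 * (I1 - lz2)
        + coef_inv / lz2
    )
    return S2, S_zz, W


def _params_arrays(params: MaterialParams):
    return (
        params.c1,
        params.c2,
        params.D1,
        params.D2,
        params.K1,
        params.K2,
        params.anisotropic,
        params.kappa_vol,
    )


def strain_energy(state: DeformationState, params: MaterialParams) -> float:
    """Energy density W (kPa) at *state*; zero at the reference configuration."""
    if state.J <= 0.0:
        raise ValueError("inverted state: J <= 0")
    c1, c2, D1, D2, K1, K2, aniso, kappa = _params_arrays(params)
    I4 = state.I4 if params.anisotropic else 1.0
    return float(
        _energy_vec(state.I1, state.I2, I4, state.J, c1, c2, D1, D2, K1, K2, aniso, kappa)
    )


def cauchy_stress(state: DeformationState, params: MaterialParams) -> np.ndarray:
    """3x3 Cauchy stress (kPa), sigma = (1/J) X S X^T with analytic S = 2 dW/dC."""
    if state.J <= 0.0:
        raise ValueError("inverted state: J <= 0")
    fiber = state.fiber if params.anisotropic else np.asarray(params.fiber_direction)
    S2, S_zz, _ = pk2_inplane_vec(
        state.F, state.lambda_z, fiber, *_params_arrays(params)
    )
    sigma = np.zeros((3, 3))
    sigma[:2, :2] = state.F @ S2 @ state.F.T / state.J
    sigma[2, 2] = state.lambda_z * S_zz * state.lambda_z / state.J
    return sigma


def principal_values(tensor: np.ndarray, atol: float = 1e-8) -> tuple[float, float]:
    """(max, min) principal values of a symmetric tensor.

    Accepts 2x2 or 3x3; asymmetry beyond *atol* (relative to the largest
    entry) is an error rather than being silently symmetrized.
    """
    T = np.asarray(tensor, dtype=float)
    scale = max(np.abs(T).max(), 1.0)
    if not np.allclose(T, T.T, atol=atol * scale):
        raise ValueError("tensor is not symmetric")
    w = np.linalg.eigvalsh(T)
    return float(w[-1]), float(w[0])
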