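"""Pointwise morphoelastic kinematics and the neo-Hookean stress response.

Atrophy is modeled as a stress-free multiplicative shrink of the deformation
gradient: ``F = Fe · Fa`` with ``Fa = υ^{1/3} I``, where the retention factor
``υ ∈ (0, 1]`` is the fraction of original tissue volume a material point
keeps (``υ = 1``: no loss). Only the elastic part ``Fe = F / υ^{1/3}``
generates stress, through a quasi-incompressible compressible neo-Hookean
energy

    W(Fe) = μ/2 (tr(be) − 2 − 2 ln Je) + κ/2 (ln Je)²,   be = Fe·Feᵀ,

with κ = kappa_ratio · μ enforcing near-incompressibility of the *elastic*
response (the atrophy shrink itself is volume-changing by design).

2D convention
-------------
All tensors are in-plane 2×2. The per-direction atrophy stretch υ^{1/3}
is applied in-plane, so the atrophy Jacobian is Ja = υ^{2/3} and the
elastic Jacobian is Je = J / υ^{2/3}. A free body therefore shrinks
linearly by υ^{1/3}, matching the three-dimensional per-direction stretch;
see docs/methods.md for the discussion of this plane reduction.

Units: stresses and moduli in kPa, lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRAY",
    "WHITE",
    "MaterialParams",
    "AtrophyField",
    "LocalKinematics",
    "LocalStress",
    "atrophy_stretch",
    "atrophy_jacobian",
    "elastic_decompose",
    "cauchy_stress",
    "von_mises",
    "material_tangent",
    "strain_energy_density",
    "batch_pk1_and_tangent",
    "batch_cauchy",
]

GRAY = "gray"
WHITE = "white"

_I2 = np.eye(2)


class DomainError(ValueError):
    """Input outside the physical domain of the model (υ, J, Je bounds)."""


class InvertedElementError(RuntimeError):
    """det(F) ≤ 0: the deformation locally inverts material."""

    def __init__(self, message: str, element: int | None = None,
                 increment: int | None = None):
        super().__init__(message)
        self.element = element
        self.increment = increment


@dataclass(frozen=True)
class MaterialParams:
    """Gray/white shear moduli and the quasi-incompressibility ratio.

    Defaults are the triaxial-test moduli for human gray and white matter
    (2.07 and 1.15 kPa) with κ = 100·μ.
    """

    mu_gray: float = 2.07      # kPa
    mu_white: float = 1.15     # kPa
    kappa_ratio: float = 100.0  # κ/μ, dimensionless
    reduction: str = "in-plane"  # fixed 2×2 in-plane formulation

    def __post_init__(self):
        if self.mu_gray <= 0 or self.mu_white <= 0:
            raise DomainError("shear moduli must be positive")
        if self.kappa_ratio < 10:
            raise DomainError("kappa_ratio must be ≥ 10 (quasi-incompressible)")
        if self.reduction != "in-plane":
            raise DomainError("only the in-plane 2×2 reduction is supported")

    def mu_of(self, region: str) -> float:
        if region == GRAY:
            return self.mu_gray
        if region == WHITE:
            return self.mu_white
        raise KeyError(f"unknown tissue region {region!r}; expected 'gray' or 'white'")

    def kappa_of(self, region: str) -> float:
        return self.kappa_ratio * self.mu_of(region)


@dataclass
class AtrophyField:
    """Per-element volume-retention factor υ (0 < υ ≤ 1: loss only)."""

    upsilon: np.ndarray

    def __post_init__(self):
        self.upsilon = np.asarray(self.upsilon, dtype=float)
        if np.any(self.upsilon <= 0) or np.any(self.upsilon > 1):
            raise DomainError("retention factor υ must satisfy 0 < υ ≤ 1")


@dataclass
class LocalKinematics:
    """Multiplicative split of an in-plane deformation gradient."""

    F: np.ndarray          # 2×2 total deformation gradient
    J: float               # det(F)
    lambda_a: float        # atrophy stretch υ^{1/3}
    Fe: np.ndarray         # elastic tensor F / λa
    Je: float              # elastic Jacobian J / λa²


@dataclass
class LocalStress:
    sigma: np.ndarray      # 2×2 symmetric Cauchy stress, kPa
    von_mises: float       # kPa


def atrophy_stretch(upsilon: float) -> float:
    """Per-direction atrophy stretch λa = υ^{1/3}."""
    if not (0.0 < upsilon <= 1.0):
        raise DomainError(f"retention factor υ={upsilon} outside (0, 1]")
    return float(upsilon) ** (1.0 / 3.0)


def atrophy_jacobian(upsilon: float) -> float:
    """In-plane atrophy Jacobian Ja = det(Fa) = υ^{2/3}."""
    return atrophy_stretch(upsilon) ** 2


def elastic_decompose(F: np.ndarray, upsilon: float) -> LocalKinematics:
    """Split F into elastic and atrophy parts: Fe = F/λa, Je = J/λa²."""
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvertedElementError(f"det(F) = {J:.3e} ≤ 0")
    lam = atrophy_stretch(upsilon)
    Fe = F / lam
    return LocalKinematics(F=F, J=J, lambda_a=lam, Fe=Fe, Je=J / lam**2)


def cauchy_stress(kin: LocalKinematics, mu: float, kappa: float) -> LocalStress:
    """σ = (1/Je)[μ(be − I) + κ ln(Je) I]; zero at Fe = I."""
    Je = kin.Je
    if Je <= 0.0:
        raise DomainError(f"elastic Jacobian Je = {Je:.3e} ≤ 0")
    be = kin.Fe @ kin.Fe.T
    sigma = (mu * (be - _I2) + kappa * np.log(Je) * _I2) / Je
    sigma = 0.5 * (sigma + sigma.T)
    return LocalStress(sigma=sigma, von_mises=von_mises(sigma))


def von_mises(sigma: np.ndarray) -> float:
    """von Mises stress of the in-plane σ embedded as 3×3 with σi3 = 0.

    sqrt(3/2 · s:s) with s the 3D deviator; rotation-invariant in plane,
    √3·τ for pure in-plane shear τ, and equal to |s| for uniaxial stress s.
    """
    s11, s22, s12 = sigma[0, 0], sigma[1, 1], sigma[0, 1]
    p = (s11 + s22) / 3.0  # mean stress of the 3×3 embedding
    d11, d22, d33 = s11 - p, s22 - p, -p
    return float(np.sqrt(1.5 * (d11**2 + d22**2 + d33**2 + 2 * s12**2)))


def strain_energy_density(kin: LocalKinematics, mu: float, kappa: float) -> float:
    """Stored energy per unit *reference* area: ψ0 = Ja · W(Fe, Je)."""
    Je = kin.Je
    if Je <= 0.0:
        raise DomainError("Je ≤ 0")
    be_tr = float(np.sum(kin.Fe**2))
    W = 0.5 * mu * (be_tr - 2.0 - 2.0 * np.log(Je)) + 0.5 * kappa * np.log(Je) ** 2
    return kin.lambda_a**2 * W


_VOIGT = [(0, 0), (1, 1), (0, 1)]


def material_tangent(kin: LocalKinematics, mu: float, kappa: float) -> np.ndarray:
    """Material tangent dS/dE in Voigt form (3×3, engineering shear).

    S is the second Piola-Kirchhoff stress of the elastic energy with
    respect to the intermediate (atrophied) configuration, E the elastic
    Green-Lagrange strain. Major symmetry holds exactly; at Fe = I the
    matrix is the isotropic linear-elastic tangent with shear modulus μ
    and (2D) Lamé parameter κ.
    """
    Fe = kin.Fe
    C = Fe.T @ Fe
    Ci = np.linalg.inv(C)
    lnJe = 0.5 * np.log(np.linalg.det(C))
    coef = 2.0 * (mu - kappa * lnJe)
    D = np.empty((3, 3))
    for a, (i, j) in enumerate(_VOIGT):
        for b, (k, l) in enumerate(_VOIGT):
            sym = 0.5 * (Ci[i, k] * Ci[j, l] + Ci[i, l] * Ci[j, k])
            D[a, b] = coef * sym + kappa * Ci[i, j] * Ci[k, l]
    return 0.5 * (D + D.T)


def second_pk_stress(kin: LocalKinematics, mu: float, kappa: float) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = μ(I − C⁻¹) + κ ln(Je) C⁻¹ (2×2)."""
    C = kin.Fe.T @ kin.Fe
    Ci = np.linalg.inv(C)
    lnJe = 0.5 * np.log(np.linalg.det(C))
    return mu * (_I2 - Ci) + kappa * lnJe * Ci


# ---------------------------------------------------------------------------
# Vectorized element-batch kernels used by the assembler.
# ---------------------------------------------------------------------------

def batch_pk1_and_tangent(F: np.ndarray, lam_a: np.ndarray, mu: np.ndarray,
                          kappa: np.ndarray, want_tangent: bool = True):
    """First Piola-Kirchhoff stress P = ∂(Ja·W)/∂F and tangent ∂P/∂F.

    Parameters are batched over elements: F is (n,2,2), the rest (n,).
    Returns (P, A, J) with P (n,2,2), A (n,2,2,2,2) or None, J (n,).
    Raises InvertedElementError when any det(F) ≤ 0.

    With Ja = λa² and Fe = F/λa one gets P = λa·Pe(Fe) and
    ∂P/∂F = ∂Pe/∂Fe evaluated at Fe:
        A_ijkl = μ δik δjl + (μ − κ lnJe) Gi_il Gi_kj + κ Gi_ij Gi_kl,
    Gi = Fe^{-T}. Major symmetry A_ijkl = A_klij holds.
    """
    J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    if np.any(J <= 0.0):
        bad = int(np.argmin(J))
        raise InvertedElementError(
            f"element {bad}: det(F) = {J[bad]:.3e} ≤ 0", element=bad)
    Fe = F / lam_a[:, None, None]
    Je = J / lam_a**2
    lnJe = np.log(Je)
    # Fe^{-T}
    Gi = np.empty_like(Fe)
    Gi[:, 0, 0] = Fe[:, 1, 1]
    Gi[:, 0, 1] = -Fe[:, 1, 0]
    Gi[:, 1, 0] = -Fe[:, 0, 1]
    Gi[:, 1, 1] = Fe[:, 0, 0]
    Gi /= Je[:, None, None]
    Pe = mu[:, None, None] * (Fe - Gi) + (kappa * lnJe)[:, None, None] * Gi
    P = lam_a[:, None, None] * Pe
    if not want_tangent:
        return P, None, J
    n = F.shape[0]
    A = np.zeros((n, 2, 2, 2, 2))
    muv = mu[:, None, None, None, None]
    c2 = (mu - kappa * lnJe)[:, None, None, None, None]
    kv = kappa[:, None, None, None, None]
    eye = np.einsum("ik,jl->ijkl", _I2, _I2)[None]
    t2 = np.einsum("nil,nkj->nijkl", Gi, Gi)
    t3 = np.einsum("nij,nkl->nijkl", Gi, Gi)
    A = muv * eye + c2 * t2 + kv * t3
    return P, A, J


def batch_cauchy(F: np.ndarray, lam_a: np.ndarray, mu: np.ndarray,
                 kappa: np.ndarray):
    """Batched Cauchy stress and von Mises. Returns (sigma (n,2,2), vm (n,))."""
    J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    if np.any(J <= 0.0):
        bad = int(np.argmin(J))
        raise InvertedElementError(
            f"element {bad}: det(F) = {J[bad]:.3e} ≤ 0", element=bad)
    Fe = F / lam_a[:, None, None]
    Je = J / lam_a**2
    be = np.einsum("nij,nkj->nik", Fe, Fe)
    sigma = (mu[:, None, None] * (be - _I2[None])
             + (kappa * np.log(Je))[:, None, None] * _I2[None]) / Je[:, None, None]
    s11, s22, s12 = sigma[:, 0, 0], sigma[:, 1, 1], sigma[:, 0, 1]
    p = (s11 + s22) / 3.0
    vm = np.sqrt(1.5 * ((s11 - p) ** 2 + (s22 - p) ** 2 + p**2 + 2 * s12**2))
    return sigma, vm


def batch_energy(F: np.ndarray, lam_a: np.ndarray, mu: np.ndarray,
                 kappa: np.ndarray) -> np.ndarray:
    """Batched reference-area energy density Ja·W(Fe)."""
    J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    if np.any(J <= 0.0):
        raise InvertedElementError("det(F) ≤ 0 in energy evaluation")
    Je = J / lam_a**2
    tr_be = np.sum(F**2, axis=(1, 2)) / lam_a**2
    W = 0.5 * mu * (tr_be - 2.0 - 2.0 * np.log(Je)) + 0.5 * kappa * np.log(Je) ** 2
    return lam_a**2 * W
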