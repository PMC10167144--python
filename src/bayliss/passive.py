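"""Passive polyconvex strain energy and stresses.

The isotropic part (elastin-rich matrix) is neo-Hookean with a
volumetric penalty enforcing near-incompressibility,

    Psi_iso = alpha1 (I1 I3^{-1/3} - 3) + alpha2 (I3^alpha3 + I3^{-alpha3} - 2),

and each collagen-fiber family contributes the transversely isotropic
term

    Psi_ti = alpha4 <K3 - 2>^alpha5,   K3 = I1 I4 - I5,

which switches off in fiber compression through the Macaulay bracket
(K3 = 2 in every stress-free configuration).  Stresses follow from
S = 2 dPsi/dC; the analytic derivative implemented here is validated
against complex-step differentiation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidDeformationError
from .kinematics import DeformationState, FiberFrame, InvariantSet, compute_invariants
from .params import PassiveParams
from .scalarmath import macaulay, spow


@dataclass(frozen=True)
class StressResult:
    """Second Piola-Kirchhoff stress S, Cauchy stress sigma (both kPa)
    and, optionally, the 6x6 material tangent 2 dS/dC in symmetric
    (Voigt) notation."""

    S: np.ndarray
    sigma: np.ndarray
    tangent: np.ndarray | None = None


def psi_passive_isotropic(inv: InvariantSet, p: PassiveParams):
    """Isotropic passive energy density (kPa). Zero at the reference state."""
    if inv.I3.real <= 0.0:
        raise InvalidDeformationError("I3 must be positive")
    iso = p.alpha1 * (inv.I1 * spow(inv.I3, -1.0 / 3.0) - 3.0)
    vol = p.alpha2 * (spow(inv.I3, p.alpha3) + spow(inv.I3, -p.alpha3) - 2.0)
    return iso + vol


def psi_passive_ti(K3, p: PassiveParams):
    """Fiber energy density (kPa) for one family; zero whenever K3 <= 2."""
    m = macaulay(K3 - 2.0)
    if m == 0.0:
        return 0.0 * m
    return p.alpha4 * spow(m, p.alpha5)


def psi_passive_total(inv: InvariantSet, p: PassiveParams):
    return psi_passive_isotropic(inv, p) + sum(psi_passive_ti(k3, p) for k3 in inv.K3)


def passive_pk2_from_C(C: np.ndarray, frame: FiberFrame, p: PassiveParams) -> np.ndarray:
    """Analytic S = 2 dPsi_p/dC (works for real and complex C)."""
    C = np.asarray(C)
    inv = compute_invariants(C, frame, check=False)
    if inv.I3.real <= 0.0:
        raise InvalidDeformationError("I3 must be positive")
    eye = np.eye(3, dtype=C.dtype)
    Cinv = np.linalg.inv(C)
    I3m13 = spow(inv.I3, -1.0 / 3.0)
    # d/dC of alpha1 (I1 I3^{-1/3} - 3)
    S = p.alpha1 * (I3m13 * eye - (inv.I1 / 3.0) * I3m13 * Cinv)
    # d/dC of the volumetric penalty, with dI3/dC = I3 C^{-1}
    S = S + p.alpha2 * p.alpha3 * (spow(inv.I3, p.alpha3) - spow(inv.I3, -p.alpha3)) * Cinv
    # fiber terms: dK3/dC = I4 I + I1 M - (CM + MC)
    for a, i4, k3 in zip(frame.directions, inv.I4, inv.K3):
        m = macaulay(k3 - 2.0)
        if m == 0.0:
            continue
        M = np.outer(a, a).astype(C.dtype)
        dK3 = i4 * eye + inv.I1 * M - (C @ M + M @ C)
        S = S + p.alpha4 * p.alpha5 * spow(m, p.alpha5 - 1.0) * dK3
    return 2.0 * S


def push_forward(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Cauchy stress sigma = (det F)^{-1} F S F^T."""
    J = np.linalg.det(F)
    return (F @ S @ F.T) / J


def passive_pk2(state: DeformationState, frame: FiberFrame, p: PassiveParams) -> StressResult:
    """Passive stress response at a deformation state."""
    S = passive_pk2_from_C(state.C, frame, p)
    sigma = push_forward(state.F, S)
    return StressResult(S=S, sigma=sigma)
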