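"""Active smooth-muscle mechanics: multiplicative stretch split,
active energy/stress and the Hill-type evolution of the active stretch.

The fiber stretch is split multiplicatively, lam = lam_a * lam_e, so
the active stretch can never turn negative (the known failure mode of
additive splits at large elastic strain).  Only attached cross-bridges
(states C and D) bear elastic stress,

    Psi_a = mu_a/2 (nC + nD)(lam_e - 1)^2,   P_a = mu_a (nC + nD)(lam_e - 1),

and cycling cross-bridges drive the contraction with P_c = kappa nC via
the hyperbolic (Hill-type) rate law

    d(lam_a)/dt = beta1 (P_a - P_c)/(P_a + beta2),

negative (contracting) while the driving stress exceeds the active
stress, zero at the isometric equilibrium P_a = P_c.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemistry import FiberChemState
from .errors import IntegrationError, ParameterError
from .params import ActiveParams

NEWTON_TOL = 1e-12
NEWTON_MAXIT = 50


@dataclass
class FiberMechState:
    """Mechanical state of one fiber family under the multiplicative split."""

    lam_a: float
    lam_e: float

    @classmethod
    def initial(cls, p: ActiveParams) -> "FiberMechState":
        return cls(lam_a=p.lam_a_start, lam_e=1.0)


def psi_active(nC, nD, lam_e, p: ActiveParams):
    """Active strain-energy density (kPa)."""
    d = lam_e - 1.0
    return 0.5 * p.mu_a * (nC + nD) * d * d


def active_stress(nC, nD, lam_e, p: ActiveParams):
    """Elastic-stretch conjugate active stress mu_a (nC + nD)(lam_e - 1)
    = dPsi_a/d(lam_e) (kPa)."""
    return p.mu_a * (nC + nD) * (lam_e - 1.0)


def active_stress_hill(nC, nD, lam_e, lam_a, p: ActiveParams):
    """Total-stretch conjugate active stress P_a = dPsi_a/d(lam) at fixed
    lam_a, i.e. mu_a (nC + nD)(lam_e - 1)/lam_a (kPa).

    This is the stress entering the Hill-type rate law: at the isometric
    balance P_a = P_c it reproduces the reported end states (elastic
    stretch ~2.25 at ~25% cycling cross-bridges), which the lam_e
    conjugate stress cannot.
    """
    return p.mu_a * (nC + nD) * (lam_e - 1.0) / lam_a


def driving_stress(nC, p: ActiveParams):
    """Driving stress of the cycling cross-bridges, P_c = kappa nC (kPa)."""
    return p.kappa * nC


def lam_a_rate(P_a, P_c, p: ActiveParams):
    """Hill-type active stretch rate beta1 (P_a - P_c)/(P_a + beta2) (1/s)."""
    denom = P_a + p.beta2
    if denom.real <= 0.0:
        raise ParameterError(f"Hill denominator P_a + beta2 = {denom} must be positive")
    return p.beta1 * (P_a - P_c) / denom


def step_active(
    state: FiberMechState,
    lam_total,
    chem: FiberChemState,
    dt: float,
    p: ActiveParams,
) -> FiberMechState:
    """One backward-Euler step of the active stretch.

    The total-stretch update is first absorbed elastically (lam_e =
    lam/lam_a with the old lam_a), then lam_a is advanced implicitly
    with P_a evaluated at the end-of-step elastic stretch and P_c held
    at its end-of-chemistry-step value; finally the multiplicative
    constraint lam = lam_a lam_e is restored exactly.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    n_att = chem.nC + chem.nD
    P_c = driving_stress(chem.nC, p)
    la_old = state.lam_a

    def g_dg(la):
        lam_e = lam_total / la
        P_a = active_stress_hill(chem.nC, chem.nD, lam_e, la, p)
        g = la - la_old - dt * lam_a_rate(P_a, P_c, p)
        # P_a = mu_a n (lam/la^2 - 1/la)
        dPa_dla = p.mu_a * n_att * (1.0 / (la * la) - 2.0 * lam_total / (la * la * la))
        drate_dPa = p.beta1 * (p.beta2 + P_c) / (P_a + p.beta2) ** 2
        dg = 1.0 - dt * drate_dPa * dPa_dla
        return g, dg

    la = la_old
    g, dg = g_dg(la)
    for _ in range(NEWTON_MAXIT):
        if abs(g) < NEWTON_TOL:
            la = la - g / dg  # Newton polish (complex-step exactness)
            break
        step = -g / dg
        alpha = 1.0
        for _ in range(40):
            la_try = la + alpha * step
            if la_try.real > 0.0:
                g_try, dg_try = g_dg(la_try)
                if abs(g_try) < (1.0 - 1e-4 * alpha) * abs(g):
                    break
            alpha *= 0.5
        else:
            raise IntegrationError("active-stretch backtracking stalled", residual=float(abs(g)))
        la, g, dg = la_try, g_try, dg_try
    else:
        raise IntegrationError("active-stretch Newton did not converge", residual=float(abs(g)))
    if la.real <= 0.0:
        raise IntegrationError(f"active stretch became non-positive: {la}")
    return FiberMechState(lam_a=la, lam_e=lam_total / la)
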