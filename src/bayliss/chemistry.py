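"""Four-state cross-bridge kinetics with stretch-dependent MLCK and
MLCP regulation.

Myosin heads cycle between four states: A (detached, dephosphorylated),
B (detached, phosphorylated), C (attached, phosphorylated, cycling) and
D (attached, dephosphorylated -- the latch state).  Phosphorylation
(k1 = k6) follows MLCK activity driven by intracellular calcium; dephos-
phorylation (k2 = k5) follows MLCP activity.  Two stretch-sensing
mechanisms close the loop:

* calcium-dependent: the calcium concentration is a function of the
  excess of fiber stretch over a moving reference stretch lam_c_bar,
  whose bounded evolution drives calcium toward a stretch-dependent
  target -- fast inflow, slower decay;
* calcium-independent: MLCP activity k25 evolves toward a
  stretch-dependent target through a bounded rate driven by a second
  reference stretch lam_p_bar, modelling slow stretch-induced MLCP
  inhibition.

All evolution laws are four-parameter sigmoids whose offsets are
constructed so the rate vanishes exactly when the driving difference is
zero; penalty terms keep k25 non-negative and bound lam - lam_p_bar
from below.

Time integration is backward Euler with local Newton iterations: the
lam_c_bar equation is scalar, the (k25, lam_p_bar) pair is solved as a
coupled 2x2 system with analytic Jacobian, and the fraction ODEs become
a 4x4 linear solve whose matrix preserves nA+nB+nC+nD = 1 exactly.

Everything on this path accepts complex arguments so the consistent
tangent of the full constitutive update can be obtained by complex-step
differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import null_space

from .errors import IntegrationError, ParameterError
from .params import ChemParams
from .scalarmath import inv_logistic, is_complex, macaulay, sexp, ssqrt

NEWTON_TOL = 1e-10
NEWTON_MAXIT = 50


@dataclass
class FiberChemState:
    """Chemical state of one fiber family."""

    nA: float
    nB: float
    nC: float
    nD: float
    k25: float  # 1/s, MLCP activity (= k2 = k5)
    lam_c_bar: float  # calcium reference stretch
    lam_p_bar: float  # MLCP reference stretch
    ca: float = 0.0  # uM, last evaluated calcium concentration

    @classmethod
    def initial(cls, p: ChemParams) -> "FiberChemState":
        return cls(
            nA=1.0,
            nB=0.0,
            nC=0.0,
            nD=0.0,
            k25=p.k25_start,
            lam_c_bar=p.lamc_start,
            lam_p_bar=p.lamp_start,
            ca=0.0,
        )

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.nA, self.nB, self.nC, self.nD])

    def validate(self, tol: float = 1e-8) -> None:
        nA, nB, nC, nD = self.nA, self.nB, self.nC, self.nD
        if abs((nA + nB + nC + nD).real - 1.0) > 1e-10:
            raise IntegrationError(
                f"fraction conservation violated: sum={nA + nB + nC + nD}"
            )
        lo, hi = -tol, 1.0 + tol
        for v in (nA, nB, nC, nD):
            if not (lo <= v.real <= hi):
                raise IntegrationError(f"fractions out of [0,1]: {self.fractions}")
        if self.k25.real < -tol:
            raise IntegrationError(f"negative MLCP activity k25={self.k25}")


# ---------------------------------------------------------------- rates


def mlck_rate(ca, p: ChemParams):
    """MLCK activity k_{1/6} = eta ca^2 / (ca^2 + ca50^2), in [0, eta)."""
    return p.eta * ca * ca / (ca * ca + p.ca50 * p.ca50)


def calcium(lam, lam_c_bar, p: ChemParams):
    """Stretch-dependent calcium concentration gamma1 <lam - lam_c_bar>^2 (uM)."""
    d = macaulay(lam - lam_c_bar)
    return p.gamma1 * d * d


def calcium_target(lam, p: ChemParams):
    """Steady-state calcium at held stretch: gamma3 lam^2/(lam^2 + lam50c^2)."""
    l2 = lam * lam
    return p.gamma3 * l2 / (l2 + p.lambda50_c * p.lambda50_c)


def _sigmoid_rate(x, rmin, rmax, gamma, tau):
    """rmin + (rmax - rmin)/(1 + exp(gamma (x - tau))), overflow-safe."""
    return rmin + (rmax - rmin) * inv_logistic(gamma * (x - tau))


def _sigmoid_rate_dx(x, rmin, rmax, gamma, tau):
    s = inv_logistic(gamma * (x - tau))
    return -(rmax - rmin) * gamma * s * (1.0 - s)


def lam_c_rate(delta_ca, p: ChemParams):
    """d(lam_c_bar)/dt as a bounded sigmoid of delta_ca = ca_target - ca.

    Exactly zero at delta_ca = 0 by the tau_c construction; tends to the
    maximal rate for strongly negative delta_ca (calcium overshoot ->
    lam_c_bar rises, shutting the calcium inflow off).
    """
    return _sigmoid_rate(delta_ca, p.lamc_rate_min, p.lamc_rate_max, p.gamma2, p.tau_c)


def k25_target(lam, p: ChemParams):
    """Long-time MLCP activity at held stretch: gamma6 (1 - lam/(lam50p + lam))."""
    return p.gamma6 * (1.0 - lam / (p.lambda50_p + lam))


def k25_rate(delta_lam_p, k25, p: ChemParams):
    """d(k25)/dt: sigmoid in delta_lam_p = lam - lam_p_bar, with the
    negative branch scaled by (1 - exp(-zeta1 k25)) so k25 can never be
    driven below zero."""
    constraint = 1.0 - sexp(-p.zeta1 * k25)
    sig = (p.k25_rate_max - p.k25_rate_min) * inv_logistic(p.gamma4 * (delta_lam_p - p.tau_p))
    return p.k25_rate_min * constraint + sig


def lam_p_rate(delta_k25, delta_lam_p, p: ChemParams):
    """d(lam_p_bar)/dt: sigmoid in delta_k25 = k25_target - k25 minus a
    barrier term that keeps delta_lam_p above delta_lamp_min."""
    sig = _sigmoid_rate(delta_k25, p.lamp_rate_min, p.lamp_rate_max, p.gamma5, p.tau_k)
    barrier = p.lamp_rate_max * sexp(-p.zeta2 * (delta_lam_p - p.delta_lamp_min))
    return sig - barrier


def hai_murphy_matrix(k16, k25, p: ChemParams, dtype=None):
    """4x4 rate matrix of the four-state kinetics (columns sum to zero)."""
    for name, val in (("k_{1/6}", k16), ("k_{2/5}", k25)):
        if val.real < 0.0:
            raise ParameterError(f"negative reaction rate {name} = {val} is non-physiological")
    if dtype is None:
        dtype = complex if is_complex(k16, k25) else float
    k1 = k6 = k16
    k2 = k5 = k25
    return np.array(
        [
            [-k1, k2, 0.0, p.k7],
            [k1, -k2 - p.k3, p.k4, 0.0],
            [0.0, p.k3, -p.k4 - k5, k6],
            [0.0, 0.0, k5, -k6 - p.k7],
        ],
        dtype=dtype,
    )


def hai_murphy_rhs(state: FiberChemState, k16, p: ChemParams) -> np.ndarray:
    """Time derivatives of the four myosin fractions."""
    A = hai_murphy_matrix(k16, state.k25, p)
    return A @ state.fractions


# ------------------------------------------------------- implicit steps


def _solve_lam_c(lam, lamc_old, dt, p: ChemParams):
    """Backward-Euler step of the lam_c_bar evolution.

    The rate is bounded, so the implicit root lies in lamc_old +
    dt*[rate_min, rate_max]; a bracketed (safeguarded) Newton iteration
    is therefore globally convergent even when the sigmoid saturates.
    The residual is strictly increasing in lam_c_bar.
    """
    catar = calcium_target(lam, p)

    def g_dg(x):
        dca = catar - calcium(lam, x, p)
        g = x - lamc_old - dt * lam_c_rate(dca, p)
        ddca_dx = 2.0 * p.gamma1 * macaulay(lam - x)
        dg = 1.0 - dt * _sigmoid_rate_dx(dca, p.lamc_rate_min, p.lamc_rate_max, p.gamma2, p.tau_c) * ddca_dx
        return g, dg

    lo = (lamc_old + dt * p.lamc_rate_min).real - 1e-14
    hi = (lamc_old + dt * p.lamc_rate_max).real + 1e-14
    x = lamc_old
    if not (lo <= x.real <= hi):
        x = 0.5 * (lo + hi) + 0.0 * x
    g = None
    for _ in range(NEWTON_MAXIT):
        g, dg = g_dg(x)
        if abs(g) < NEWTON_TOL:
            # one pure Newton polish step keeps the complex-step
            # derivative information exact through the iteration
            return x - g / dg
        if g.real > 0.0:
            hi = min(hi, x.real)
        else:
            lo = max(lo, x.real)
        x_new = x - g / dg
        if not (lo <= x_new.real <= hi):
            x_new = 0.5 * (lo + hi) + 0.0 * x  # bisection fallback
        x = x_new
    raise IntegrationError("lam_c_bar iteration did not converge", residual=float(abs(g)))


def _solve_k25_lam_p(lam, k_old, lp_old, dt, p: ChemParams):
    """Coupled backward-Euler step of (k25, lam_p_bar): 2x2 Newton with
    analytic Jacobian."""
    ktar = k25_target(lam, p)

    def residual(k, lp):
        dlp = lam - lp
        dk = ktar - k
        f1 = k - k_old - dt * k25_rate(dlp, k, p)
        f2 = lp - lp_old - dt * lam_p_rate(dk, dlp, p)
        return f1, f2

    def jacobian(k, lp):
        dlp = lam - lp
        dk = ktar - k
        dkrate_dk = p.k25_rate_min * p.zeta1 * sexp(-p.zeta1 * k)
        s = inv_logistic(p.gamma4 * (dlp - p.tau_p))
        dkrate_ddlp = -(p.k25_rate_max - p.k25_rate_min) * p.gamma4 * s * (1.0 - s)
        dprate_ddk = _sigmoid_rate_dx(dk, p.lamp_rate_min, p.lamp_rate_max, p.gamma5, p.tau_k)
        dprate_ddlp = p.lamp_rate_max * p.zeta2 * sexp(-p.zeta2 * (dlp - p.delta_lamp_min))
        # chain rule: d(dlp)/d(lp) = -1, d(dk)/d(k) = -1
        j11 = 1.0 - dt * dkrate_dk
        j12 = dt * dkrate_ddlp
        j21 = dt * dprate_ddk
        j22 = 1.0 + dt * dprate_ddlp
        return j11, j12, j21, j22

    def newton_step(k, lp, f1, f2):
        j11, j12, j21, j22 = jacobian(k, lp)
        det = j11 * j22 - j12 * j21
        dk_step = (-f1 * j22 + f2 * j12) / det
        dlp_step = (f1 * j21 - f2 * j11) / det
        return dk_step, dlp_step

    k, lp = k_old, lp_old
    # after a sudden stretch drop the old lam_p_bar can sit far beyond the
    # zeta2 barrier, where the residual is an exponential cliff that plain
    # Newton descends only ~1/zeta2 per iteration; start at the wall instead
    if (lam - lp).real < p.delta_lamp_min:
        lp = lam - p.delta_lamp_min
    f1, f2 = residual(k, lp)
    norm = abs(f1) + abs(f2)
    for _ in range(NEWTON_MAXIT):
        if norm < NEWTON_TOL:
            # pure Newton polish to transmit complex-step derivatives
            dk_step, dlp_step = newton_step(k, lp, f1, f2)
            return k + dk_step, lp + dlp_step
        dk_step, dlp_step = newton_step(k, lp, f1, f2)
        alpha = 1.0
        for _ in range(40):
            k_try = k + alpha * dk_step
            lp_try = lp + alpha * dlp_step
            f1_try, f2_try = residual(k_try, lp_try)
            norm_try = abs(f1_try) + abs(f2_try)
            if norm_try < (1.0 - 1e-4 * alpha) * norm:
                break
            alpha *= 0.5
        else:
            raise IntegrationError(
                "(k25, lam_p_bar) backtracking stalled", residual=float(norm)
            )
        k, lp, f1, f2, norm = k_try, lp_try, f1_try, f2_try, norm_try
    raise IntegrationError("(k25, lam_p_bar) Newton did not converge", residual=float(norm))


def step_chemistry(
    state: FiberChemState,
    lam,
    dt: float,
    p: ChemParams,
    k25_frozen: bool = False,
) -> FiberChemState:
    """One implicit (backward Euler) step of the full chemical model at
    end-of-step fiber stretch ``lam``.

    Order within the step mirrors the sequential material-point
    algorithm: the stretch-sensing rates are updated first (lam_c_bar,
    then the coupled (k25, lam_p_bar) pair), and the fraction ODEs are
    then stepped fully implicitly with the end-of-step rates.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if p.ca_const is not None:
        lamc_new = state.lam_c_bar
        ca = p.ca_const
    else:
        lamc_new = _solve_lam_c(lam, state.lam_c_bar, dt, p)
        ca = calcium(lam, lamc_new, p)
    k16 = mlck_rate(ca, p)

    if k25_frozen:
        k25_new, lamp_new = state.k25, state.lam_p_bar
    else:
        k25_new, lamp_new = _solve_k25_lam_p(lam, state.k25, state.lam_p_bar, dt, p)
        if -1e-10 < k25_new.real < 0.0:  # roundoff at the k25 = 0 barrier
            k25_new = k25_new - k25_new.real

    A = hai_murphy_matrix(k16, k25_new, p)
    lhs = np.eye(4, dtype=A.dtype) - dt * A
    n_new = np.linalg.solve(lhs, state.fractions.astype(A.dtype, copy=False))

    new = FiberChemState(
        nA=n_new[0],
        nB=n_new[1],
        nC=n_new[2],
        nD=n_new[3],
        k25=k25_new,
        lam_c_bar=lamc_new,
        lam_p_bar=lamp_new,
        ca=ca,
    )
    if not is_complex(lam, *n_new):
        new.validate()
    return new


# ------------------------------------------------------- steady state


def steady_fractions(k16: float, k25: float, p: ChemParams) -> np.ndarray:
    """Normalized null vector of the rate matrix (the kinetic steady state)."""
    A = hai_murphy_matrix(k16, k25, p, dtype=float)
    ns = null_space(A)
    if ns.shape[1] != 1:
        raise ParameterError(f"degenerate kinetics: null space dimension {ns.shape[1]}")
    n = ns[:, 0]
    n = n / n.sum()
    if np.any(n < -1e-12):
        raise ParameterError("steady-state fractions not non-negative")
    return n


def chem_steady_state(lam: float, p: ChemParams) -> FiberChemState:
    """Exact fixed point of the chemical model at indefinitely held stretch.

    Calcium settles at its target, lam_c_bar at the inverse of the
    calcium law.  (k25, lam_p_bar) solve the coupled zero-rate
    conditions; note the lam_p_bar barrier is not fully inactive at
    delta_lam_p = 0 with the default penalty constants, so the steady
    k25 sits slightly above its nominal target.  Fractions are the
    null vector of the resulting rate matrix.
    """
    if p.ca_const is not None:
        ca = p.ca_const
        lamc = p.lamc_start
    else:
        ca = calcium_target(lam, p)
        lamc = lam - ssqrt(ca / p.gamma1) if p.gamma1 > 0 else lam
    k16 = mlck_rate(ca, p)
    ktar = k25_target(lam, p)

    def zero_rates(x):
        k, lp = x
        return [
            k25_rate(lam - lp, k, p),
            lam_p_rate(ktar - k, lam - lp, p),
        ]

    sol = optimize.root(zero_rates, x0=[ktar + 0.05, lam], method="hybr", tol=1e-14)
    if not sol.success:
        raise IntegrationError("steady-state solve failed: " + sol.message)
    k25_ss, lamp_ss = sol.x
    n = steady_fractions(k16, k25_ss, p)
    return FiberChemState(
        nA=n[0], nB=n[1], nC=n[2], nD=n[3], k25=k25_ss, lam_c_bar=lamc, lam_p_bar=lamp_ss, ca=ca
    )
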