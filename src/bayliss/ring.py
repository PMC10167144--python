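"""Reduced axisymmetric thick-walled ring solver.

The pressurized arterial ring is theta-independent, axially constrained
(plane strain, lam_z = 1) and rotation-free, so the boundary value
problem is one-dimensional in the radius.  The opened, stress-free
sector with (half) opening angle phi closes onto the ring with
circumferential stretch lam_theta = k_phi r(R)/R, k_phi = pi/(pi -
phi), which induces the classical residual-stress pattern.

Discretization: 1D finite elements in the reference radius (quadratic
3-node elements with 2-point Gauss quadrature -- reduced integration,
which keeps the near-incompressibility penalty free of checkerboard
pressure modes), with one material-point history per quadrature point.
Equilibrium

    d(sigma_rr)/dr + (sigma_rr - sigma_tt)/r = 0,
    sigma_rr(r_i) = -p,  sigma_rr(r_o) = 0

is enforced in weak form with a follower pressure load; the Newton
iteration uses the consistent tangent obtained by complex-step
differentiation of the fully coupled constitutive update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrationError, ParameterError, SolverError
from .kinematics import FiberFrame, fiber_stretch
from .material_point import (
    MaterialOptions,
    MaterialState,
    constitutive_update,
    stress_diag_given_state,
    stress_resolved_diag,
)
from .params import MaterialParams

_GAUSS_XI = (-1.0 / math.sqrt(3.0), 1.0 / math.sqrt(3.0))
_CSDA_H = 1e-20


@dataclass(frozen=True)
class RingConfiguration:
    """Reference (opened, stress-free) geometry of the arterial ring.

    Radii in micrometres; ``phi_deg`` is the opening angle; the fiber
    angle beta(R) varies linearly from ``beta_inner`` at the inner wall
    to ``beta_outer`` at the outer wall.
    """

    R_i: float = 92.0
    R_o: float = 112.0
    phi_deg: float = 38.923
    n_elem: int = 4
    beta_inner: float = 10.0
    beta_outer: float = 40.0

    def __post_init__(self):
        if not (self.R_o > self.R_i > 0.0):
            raise ParameterError("require R_o > R_i > 0")
        if not (0.0 <= self.phi_deg < 180.0):
            raise ParameterError("opening angle must lie in [0, 180) degrees")
        if self.n_elem < 1:
            raise ParameterError("need at least one radial element")

    @property
    def k_phi(self) -> float:
        """Closing factor pi/(pi - phi)."""
        return math.pi / (math.pi - math.radians(self.phi_deg))

    def beta_at(self, R: float) -> float:
        s = (R - self.R_i) / (self.R_o - self.R_i)
        return self.beta_inner + s * (self.beta_outer - self.beta_inner)


@dataclass(frozen=True)
class _QuadPoint:
    nodes: tuple[int, int, int]  # global node indices of the element
    R: float
    w: float  # gauss weight * element Jacobian
    N: np.ndarray  # shape values at the point (3,)
    dN: np.ndarray  # shape derivatives dN/dR (3,)
    frame: FiberFrame


class RingMesh:
    """Radial discretization: quadratic elements, nodes in R and
    quadrature-point data."""

    def __init__(self, ring: RingConfiguration):
        self.ring = ring
        self.nodes = np.linspace(ring.R_i, ring.R_o, 2 * ring.n_elem + 1)
        self.k_phi = ring.k_phi
        h = (ring.R_o - ring.R_i) / ring.n_elem
        qps: list[_QuadPoint] = []
        for e in range(ring.n_elem):
            conn = (2 * e, 2 * e + 1, 2 * e + 2)
            R_mid = self.nodes[conn[1]]
            for xi in _GAUSS_XI:
                R = R_mid + 0.5 * h * xi
                N = np.array([0.5 * xi * (xi - 1.0), 1.0 - xi * xi, 0.5 * xi * (xi + 1.0)])
                dN_dxi = np.array([xi - 0.5, -2.0 * xi, xi + 0.5])
                dN = dN_dxi / (0.5 * h)
                frame = FiberFrame.from_beta(ring.beta_at(R))
                qps.append(_QuadPoint(nodes=conn, R=R, w=0.5 * h, N=N, dN=dN, frame=frame))
        self.qps = qps

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_qp(self) -> int:
        return len(self.qps)

    def initial_states(self, params: MaterialParams, k25_init: float | None = None):
        return [MaterialState.initial(params, k25_init=k25_init) for _ in self.qps]

    def qp_kinematics(self, r_nodes: np.ndarray, qp: _QuadPoint):
        """(lam_r, lam_theta) at a quadrature point for nodal radii r."""
        re_ = r_nodes[list(qp.nodes)]
        lam_r = float(qp.dN @ re_)
        lam_t = self.k_phi * float(qp.N @ re_) / qp.R
        return lam_r, lam_t

    def admissible(self, r_nodes: np.ndarray) -> bool:
        """Trial radii are admissible if r > 0 and lam_r > 0 at every
        quadrature point (no local inversion)."""
        if r_nodes[0] <= 0.0:
            return False
        return all(float(qp.dN @ r_nodes[list(qp.nodes)]) > 0.0 for qp in self.qps)


def closing_map(ring: RingConfiguration, r_inner_guess: float | None = None) -> np.ndarray:
    """Incompressible closing-map predictor r(R) for the nodal radii.

    Maps the opened sector onto a closed ring with lam_r lam_theta = 1
    (lam_z = 1); the remaining free constant is chosen so the mid-wall
    circumferential stretch is one, unless ``r_inner_guess`` is given.
    """
    k = ring.k_phi
    mesh_R = np.linspace(ring.R_i, ring.R_o, 2 * ring.n_elem + 1)
    if r_inner_guess is None:
        R_mid = 0.5 * (ring.R_i + ring.R_o)
        ri2 = (R_mid / k) ** 2 - (R_mid**2 - ring.R_i**2) / k
        if ri2 <= 0.0:
            ri2 = (ring.R_i / math.sqrt(k)) ** 2
        r_inner_guess = math.sqrt(ri2)
    r2 = r_inner_guess**2 + (mesh_R**2 - ring.R_i**2) / k
    if np.any(r2 <= 0.0):
        raise SolverError("closing-map predictor produced non-positive radii")
    return np.sqrt(r2)


def _C_diag(lam_r, lam_t):
    dtype = complex if isinstance(lam_r, complex) or isinstance(lam_t, complex) else float
    C = np.zeros((3, 3), dtype=dtype)
    C[0, 0] = lam_r * lam_r
    C[1, 1] = lam_t * lam_t
    C[2, 2] = 1.0
    return C


def _qp_stress(lam_r, lam_t, state_old, dt, params, frame, opts):
    S = stress_resolved_diag(lam_r * lam_r, lam_t * lam_t, state_old, dt, params, frame, opts)
    return S[0], S[1]


def assemble_residual(
    r_nodes: np.ndarray,
    mesh: RingMesh,
    states_old: list[MaterialState],
    dt: float,
    params: MaterialParams,
    opts: MaterialOptions,
    pressure_kpa: float,
    want_jac: bool = False,
):
    """Weak-form radial equilibrium residual (and consistent Jacobian).

    Residual units are kPa*um (virtual work per radian and unit axial
    length, divided by 2*pi); zero at equilibrium.
    """
    n = mesh.n_nodes
    k = mesh.k_phi
    res = np.zeros(n)
    K = np.zeros((n, n)) if want_jac else None
    for qp, st in zip(mesh.qps, states_old):
        idx = qp.nodes
        lam_r, lam_t = mesh.qp_kinematics(r_nodes, qp)
        SRR, STT = _qp_stress(lam_r, lam_t, st, dt, params, qp.frame, opts)
        SRR, STT = SRR.real, STT.real
        common = qp.w * qp.R / k
        kR = k / qp.R
        for jl, j in enumerate(idx):
            res[j] += common * (SRR * lam_r * qp.dN[jl] + STT * lam_t * kR * qp.N[jl])
        if want_jac:
            SRR_r, STT_r = _qp_stress(lam_r + 1j * _CSDA_H, lam_t, st, dt, params, qp.frame, opts)
            SRR_t, STT_t = _qp_stress(lam_r, lam_t + 1j * _CSDA_H, st, dt, params, qp.frame, opts)
            dSRR = (SRR_r.imag / _CSDA_H, SRR_t.imag / _CSDA_H)
            dSTT = (STT_r.imag / _CSDA_H, STT_t.imag / _CSDA_H)
            for jl, j in enumerate(idx):
                for ml, m in enumerate(idx):
                    dlr = qp.dN[ml]
                    dlt = kR * qp.N[ml]
                    K[j, m] += common * (
                        (dSRR[0] * dlr + dSRR[1] * dlt) * lam_r * qp.dN[jl]
                        + SRR * qp.dN[jl] * dlr
                        + (dSTT[0] * dlr + dSTT[1] * dlt) * lam_t * kR * qp.N[jl]
                        + STT * kR * qp.N[jl] * dlt
                    )
    # follower pressure on the inner surface
    res[0] -= pressure_kpa * r_nodes[0]
    if want_jac:
        K[0, 0] -= pressure_kpa
    return res, K


@dataclass
class RingSolution:
    """Converged state of the ring at one time/pressure point."""

    ring: RingConfiguration
    mesh: RingMesh
    r_nodes: np.ndarray
    states: list[MaterialState]
    pressure_kpa: float
    time: float
    dt: float
    params: MaterialParams
    opts: MaterialOptions
    iterations: int = 0
    residual_norm: float = 0.0
    residual_history: list[float] = field(default_factory=list)
    jacobian: np.ndarray | None = None  # last consistent tangent (for warm starts)

    @property
    def d_outer(self) -> float:
        """Outer diameter (um)."""
        return 2.0 * float(self.r_nodes[-1])

    def qp_current_radii(self) -> np.ndarray:
        return np.array(
            [float(qp.N @ self.r_nodes[list(qp.nodes)]) for qp in self.mesh.qps]
        )

    def stress_profile(self) -> dict[str, np.ndarray]:
        """Transmural Cauchy stress profile at the quadrature points."""
        out = {"r": self.qp_current_radii(), "sigma_rr": [], "sigma_tt": [], "sigma_zz": []}
        for qp, st in zip(self.mesh.qps, self.states):
            lam_r, lam_t = self.mesh.qp_kinematics(self.r_nodes, qp)
            S = stress_diag_given_state(
                lam_r * lam_r, lam_t * lam_t, st.chem, st.mech, self.params, qp.frame,
                self.opts.passive_only,
            )
            J = lam_r * lam_t
            out["sigma_rr"].append(lam_r * lam_r * S[0] / J)
            out["sigma_tt"].append(lam_t * lam_t * S[1] / J)
            out["sigma_zz"].append(S[2] / J)
        return {k: np.asarray(v) for k, v in out.items()}

    def qp_diagnostics(self, qp_index: int, fiber: int = 0) -> dict[str, float]:
        """Chemo-mechanical diagnostics of one fiber family at one point."""
        from .active import active_stress_hill, driving_stress
        from .chemistry import mlck_rate

        qp = self.mesh.qps[qp_index]
        st = self.states[qp_index]
        lam_r, lam_t = self.mesh.qp_kinematics(self.r_nodes, qp)
        lam = fiber_stretch(_C_diag(lam_r, lam_t), qp.frame.directions[fiber])
        ch, me = st.chem[fiber], st.mech[fiber]
        return {
            "lam": lam,
            "lam_a": me.lam_a,
            "lam_e": me.lam_e,
            "nA": ch.nA,
            "nB": ch.nB,
            "nC": ch.nC,
            "nD": ch.nD,
            "k25": ch.k25,
            "ca": ch.ca,
            "k16": mlck_rate(ch.ca, self.params.chem),
            "P_a": active_stress_hill(ch.nC, ch.nD, me.lam_e, me.lam_a, self.params.active),
            "P_c": driving_stress(ch.nC, self.params.active),
        }


def solve_step(
    mesh: RingMesh,
    r_guess: np.ndarray,
    states_old: list[MaterialState],
    pressure_kpa: float,
    dt: float,
    params: MaterialParams,
    opts: MaterialOptions = MaterialOptions(),
    time: float = 0.0,
    max_iter: int = 40,
    atol: float | None = None,
    jac_reuse: np.ndarray | None = None,
    full_newton: bool = False,
) -> RingSolution:
    """One time/pressure step: damped (modified) Newton on the nodal
    radii with the consistent tangent; internal variables are re-solved
    for every trial geometry and committed on convergence.

    ``jac_reuse`` warm-starts the iteration with a tangent from a
    previous step (cheap quasi-Newton phase); a fresh consistent
    tangent is assembled whenever contraction degrades, so terminal
    convergence stays quadratic.
    """
    ring = mesh.ring
    if atol is None:
        atol = 1e-9 * (1.0 + abs(pressure_kpa) * ring.R_i) * mesh.n_nodes
    r = np.asarray(r_guess, dtype=float).copy()
    history: list[float] = []

    def res_only(x):
        return assemble_residual(x, mesh, states_old, dt, params, opts, pressure_kpa)[0]

    K = jac_reuse
    K_fresh = False
    if K is None:
        res, K = assemble_residual(
            r, mesh, states_old, dt, params, opts, pressure_kpa, want_jac=True
        )
        K_fresh = True
    else:
        res = res_only(r)
    norm = float(np.linalg.norm(res))
    history.append(norm)
    it = 0
    tr_attempts = 0
    last_tr_iter = -10
    slow_iters = 0

    def _tol() -> float:
        # floating-point floor of the assembled residual: the nodal
        # forces are O(|K| |r|), so meaningful residuals cannot be
        # resolved much below machine precision times that scale
        floor = 1e-14 * float(np.linalg.norm(K)) * float(np.linalg.norm(r))
        return max(atol, floor)

    while norm > _tol():
        if it >= max_iter:
            raise SolverError(
                f"ring Newton did not converge: |res|={norm:.3e} after {it} iterations"
            )
        dr = np.linalg.solve(K, -res)
        used_fresh = K_fresh
        alpha = 1.0
        accepted = False
        for _ in range(15):
            r_try = r + alpha * dr
            if not mesh.admissible(r_try):
                alpha *= 0.5
                continue
            try:
                res_try = res_only(r_try)
            except (IntegrationError, ParameterError):
                alpha *= 0.5
                continue
            norm_try = float(np.linalg.norm(res_try))
            if norm_try < (1.0 - 1e-4 * alpha) * norm or norm_try < _tol():
                accepted = True
                break
            alpha *= 0.5
        if accepted:
            r, res, norm = r_try, res_try, norm_try
            history.append(norm)
            it += 1
            K_fresh = False  # any accepted move makes the tangent stale
            if norm <= _tol():
                break
            poor = alpha < 1.0 or norm > 0.25 * history[-2]
            if poor or full_newton:
                # slow contraction: assemble the consistent tangent at the
                # new iterate (quadratic terminal convergence); count how
                # often even fresh-tangent steps contract poorly
                slow_iters = slow_iters + 1 if used_fresh else 0
                res, K = assemble_residual(
                    r, mesh, states_old, dt, params, opts, pressure_kpa, want_jac=True
                )
                K_fresh = True
            else:
                slow_iters = 0  # stale tangent contracts well: keep it
            if slow_iters < 3:
                continue
        elif not used_fresh:
            res, K = assemble_residual(
                r, mesh, states_old, dt, params, opts, pressure_kpa, want_jac=True
            )
            norm = float(np.linalg.norm(res))
            K_fresh = True
            continue
        # consistent tangent and still crawling/stuck in the stiff
        # volumetric-penalty valley: hand the global phase to a dogleg
        # trust-region solve on the same residual, then resume Newton.
        tr_allowed = tr_attempts < 3 and it - last_tr_iter >= 2
        if not tr_allowed:
            if accepted:
                slow_iters = 0
                continue
            raise SolverError(f"line search failed at |res|={norm:.3e}")
        tr_attempts += 1
        last_tr_iter = it
        slow_iters = 0
        from scipy.optimize import root as _root

        def _F(x):
            try:
                return res_only(x)
            except (IntegrationError, ParameterError):
                return np.full_like(x, 1e12)

        def _J(x):
            return assemble_residual(
                x, mesh, states_old, dt, params, opts, pressure_kpa, want_jac=True
            )[1]

        tr = _root(_F, r, jac=_J, method="hybr", tol=1e-12)
        res_tr = _F(tr.x)
        if np.linalg.norm(res_tr) < norm and mesh.admissible(tr.x):
            r = tr.x
            res = res_tr
            norm = float(np.linalg.norm(res))
            history.append(norm)
        elif not accepted:
            raise SolverError(f"trust-region fallback failed at |res|={norm:.3e}")
        res, K = assemble_residual(
            r, mesh, states_old, dt, params, opts, pressure_kpa, want_jac=True
        )
        norm = float(np.linalg.norm(res))
        K_fresh = True
        it += 1

    # commit internal variables at the converged geometry
    new_states = []
    for qp, st in zip(mesh.qps, states_old):
        lam_r, lam_t = mesh.qp_kinematics(r, qp)
        C = _C_diag(lam_r, lam_t)
        F = np.diag([lam_r, lam_t, 1.0])
        _, st_new = constitutive_update(C, st, dt, params, qp.frame, opts, F_new=F)
        st_new.time = time
        new_states.append(st_new)
    return RingSolution(
        ring=ring,
        mesh=mesh,
        r_nodes=r,
        states=new_states,
        pressure_kpa=pressure_kpa,
        time=time,
        dt=dt,
        params=params,
        opts=opts,
        iterations=it,
        residual_norm=norm,
        residual_history=history,
        jacobian=K,
    )


def solve_equilibrium(
    ring: RingConfiguration,
    pressure_kpa: float,
    params: MaterialParams,
    opts: MaterialOptions = MaterialOptions(passive_only=True),
    mesh: RingMesh | None = None,
    r_guess: np.ndarray | None = None,
    states: list[MaterialState] | None = None,
    n_continuation: int = 4,
    p_start: float = 0.0,
) -> RingSolution:
    """Static (elastic) equilibrium at a given pressure, with pressure
    continuation (from ``p_start``, matching the supplied guess) for
    robustness.  Intended for passive analyses where no history
    dependence exists."""
    mesh = mesh or RingMesh(ring)
    states = states or mesh.initial_states(params)
    r = r_guess if r_guess is not None else closing_map(ring)
    ladder = np.linspace(p_start, pressure_kpa, n_continuation + 1)
    if r_guess is None:
        ladder = np.insert(ladder, 0, 0.0)  # closing solve first
    sol = None
    for p in ladder:
        sol = solve_step(mesh, r, states, p, dt=1.0, params=params, opts=opts)
        r = sol.r_nodes
    return sol
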