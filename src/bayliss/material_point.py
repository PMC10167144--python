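"""Full constitutive update at one material point.

For a trial right Cauchy-Green tensor and committed history the update
runs, per fiber family: fiber stretch -> implicit chemistry step ->
implicit active-stretch step -> stress assembly

    S = S_passive(C) + sum_f P_a^(f) / (lam_a^(f) lam^(f)) M^(f),

where the active second Piola-Kirchhoff contribution is 2 dPsi_a/dC at
frozen internal variables.  The tangent moduli are obtained by
complex-step differentiation of the stress with the internal variables
re-solved for every perturbed C, i.e. fully coupled at the material
point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .active import FiberMechState, active_stress, step_active
from .chemistry import FiberChemState, step_chemistry
from .kinematics import FiberFrame, fiber_stretch
from .params import MaterialParams
from .passive import StressResult, passive_pk2_from_C, push_forward

CSDA_STEP = 1e-20

# Voigt index pairs for symmetric 3x3 tensors
_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]


@dataclass(frozen=True)
class MaterialOptions:
    """Scenario-level switches applied at the material point.

    ``passive_only`` skips the chemical and active model entirely;
    ``k25_frozen`` disables the calcium-independent mechanism (the MLCP
    rate stays at its initial value).  Constant-calcium overrides live
    on ChemParams (``ca_const``).
    """

    passive_only: bool = False
    k25_frozen: bool = False


@dataclass
class MaterialState:
    """Committed history at one material point: per-fiber chemical and
    mechanical states for both families, plus the time stamp."""

    chem: list[FiberChemState]
    mech: list[FiberMechState]
    time: float = 0.0

    @classmethod
    def initial(cls, params: MaterialParams, k25_init: float | None = None) -> "MaterialState":
        chem = [FiberChemState.initial(params.chem) for _ in range(2)]
        if k25_init is not None:
            for c in chem:
                c.k25 = k25_init
        mech = [FiberMechState.initial(params.active) for _ in range(2)]
        return cls(chem=chem, mech=mech, time=0.0)

    def copy(self) -> "MaterialState":
        return MaterialState(
            chem=[replace(c) for c in self.chem],
            mech=[replace(m) for m in self.mech],
            time=self.time,
        )


def stress_given_state(
    C: np.ndarray,
    chem: list[FiberChemState],
    mech: list[FiberMechState],
    params: MaterialParams,
    frame: FiberFrame,
    passive_only: bool = False,
) -> np.ndarray:
    """Total PK2 stress at C with internal variables held fixed.

    The elastic fiber stretch is re-evaluated from C (lam_e = lam/lam_a);
    lam_a and the myosin fractions act as history variables.
    """
    S = passive_pk2_from_C(C, frame, params.passive)
    if passive_only:
        return S
    for a, ch, me in zip(frame.directions, chem, mech):
        lam = fiber_stretch(C, a)
        lam_e = lam / me.lam_a
        P_a = active_stress(ch.nC, ch.nD, lam_e, params.active)
        coef = P_a / (me.lam_a * lam)
        M = np.outer(a, a).astype(C.dtype)
        S = S + coef * M
    return S


def _advance_state(
    C: np.ndarray,
    state_old: MaterialState,
    dt: float,
    params: MaterialParams,
    frame: FiberFrame,
    opts: MaterialOptions,
):
    """Run chemistry + active updates for both fibers; returns new states.

    Mirror-symmetric families under a shear-free deformation see the
    same stretch; when additionally their histories coincide (as in the
    axisymmetric ring) the second update is an exact copy of the first.
    """
    chem_new, mech_new = [], []
    lam0 = None
    for f, a in enumerate(frame.directions):
        lam = fiber_stretch(C, a)
        if f > 0 and lam == lam0 and _fiber_states_equal(state_old, 0, f):
            chem_new.append(replace(chem_new[0]))
            mech_new.append(replace(mech_new[0]))
            continue
        try:
            ch = step_chemistry(
                state_old.chem[f], lam, dt, params.chem, k25_frozen=opts.k25_frozen
            )
            me = step_active(state_old.mech[f], lam, ch, dt, params.active)
        except Exception as err:
            raise type(err)(f"fiber {f}: {err}") from err
        chem_new.append(ch)
        mech_new.append(me)
        lam0 = lam
    return chem_new, mech_new


def _fiber_states_equal(state: MaterialState, i: int, j: int) -> bool:
    a, b = state.chem[i], state.chem[j]
    ma, mb = state.mech[i], state.mech[j]
    return (
        a.nA == b.nA
        and a.nB == b.nB
        and a.nC == b.nC
        and a.nD == b.nD
        and a.k25 == b.k25
        and a.lam_c_bar == b.lam_c_bar
        and a.lam_p_bar == b.lam_p_bar
        and ma.lam_a == mb.lam_a
    )


def constitutive_update(
    C_new: np.ndarray,
    state_old: MaterialState,
    dt: float,
    params: MaterialParams,
    frame: FiberFrame,
    opts: MaterialOptions = MaterialOptions(),
    F_new: np.ndarray | None = None,
    want_tangent: bool = False,
) -> tuple[StressResult, MaterialState]:
    """Stress, optional tangent, and updated state at a material point.

    ``F_new`` is only needed for the Cauchy push-forward; if omitted,
    the symmetric square root U of C is used (rotation-free motion
    assumed, as in the ring problem).
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    C_new = np.asarray(C_new)
    if opts.passive_only:
        chem_new = [replace(c) for c in state_old.chem]
        mech_new = [replace(m) for m in state_old.mech]
    else:
        chem_new, mech_new = _advance_state(C_new, state_old, dt, params, frame, opts)

    S = stress_given_state(C_new, chem_new, mech_new, params, frame, opts.passive_only)
    if F_new is None:
        w, V = np.linalg.eigh(C_new)
        F_new = V @ np.diag(np.sqrt(w)) @ V.T
    sigma = push_forward(F_new, S)

    tangent = None
    if want_tangent:
        tangent = csda_tangent(C_new, state_old, dt, params, frame, opts)

    new_state = MaterialState(chem=chem_new, mech=mech_new, time=state_old.time + dt)
    return StressResult(S=S, sigma=sigma, tangent=tangent), new_state


def _stress_resolved(C, state_old, dt, params, frame, opts):
    """PK2 stress at trial C with internal variables re-solved from the
    committed history (complex-safe)."""
    if opts.passive_only:
        return stress_given_state(C, state_old.chem, state_old.mech, params, frame, True)
    chem_new, mech_new = _advance_state(C, state_old, dt, params, frame, opts)
    return stress_given_state(C, chem_new, mech_new, params, frame)


# ------------------------------------------------------------------
# scalar fast path for shear-free (diagonal-C) deformations, used by
# the axisymmetric ring solver where C = diag(lr^2, lt^2, 1) at every
# quadrature point; exactly equivalent to the tensor path (tested)
# but avoids all 3x3 linear algebra in the innermost loop.


def _passive_pk2_diag(c1, c2, c3, frame: FiberFrame, p):
    from .errors import InvalidDeformationError
    from .scalarmath import macaulay, spow

    I1 = c1 + c2 + c3
    I3 = c1 * c2 * c3
    if I3.real <= 0.0:
        raise InvalidDeformationError("I3 must be positive")
    I3m13 = spow(I3, -1.0 / 3.0)
    pen = p.alpha2 * p.alpha3 * (spow(I3, p.alpha3) - spow(I3, -p.alpha3))
    a1_I3m13 = p.alpha1 * I3m13
    third_I1 = I1 / 3.0
    S = [2.0 * (a1_I3m13 - (a1_I3m13 * third_I1 - pen) / ci) for ci in (c1, c2, c3)]
    for m0, m1, m2 in frame.m_diag:
        i4 = c1 * m0 + c2 * m1 + c3 * m2
        i5 = c1 * c1 * m0 + c2 * c2 * m1 + c3 * c3 * m2
        mac = macaulay(I1 * i4 - i5 - 2.0)
        if mac == 0.0:
            continue
        coef = 2.0 * p.alpha4 * p.alpha5 * spow(mac, p.alpha5 - 1.0)
        S[0] += coef * (i4 + (I1 - 2.0 * c1) * m0)
        S[1] += coef * (i4 + (I1 - 2.0 * c2) * m1)
        S[2] += coef * (i4 + (I1 - 2.0 * c3) * m2)
    return S


def stress_diag_given_state(c1, c2, chem, mech, params, frame, passive_only=False):
    """PK2 diagonal (S_rr, S_tt, S_zz) at C = diag(c1, c2, 1) with frozen
    internal variables (scalar fast path)."""
    from .scalarmath import ssqrt

    S = _passive_pk2_diag(c1, c2, 1.0, frame, params.passive)
    if not passive_only:
        mu_a = params.active.mu_a
        for (m0, m1, m2), ch, me in zip(frame.m_diag, chem, mech):
            lam = ssqrt(c1 * m0 + c2 * m1 + m2)
            coef = mu_a * (ch.nC + ch.nD) * (lam / me.lam_a - 1.0) / (me.lam_a * lam)
            S[0] += coef * m0
            S[1] += coef * m1
            S[2] += coef * m2
    return S


def _advance_state_diag(c1, c2, state_old, dt, params, frame, opts):
    """Chemistry + active update for both fibers at diagonal C (scalars)."""
    from .scalarmath import ssqrt

    chem_new, mech_new = [], []
    lam0 = None
    for f, (m0, m1, m2) in enumerate(frame.m_diag):
        lam = ssqrt(c1 * m0 + c2 * m1 + m2)
        if f > 0 and lam == lam0 and _fiber_states_equal(state_old, 0, f):
            chem_new.append(replace(chem_new[0]))
            mech_new.append(replace(mech_new[0]))
            continue
        try:
            ch = step_chemistry(
                state_old.chem[f], lam, dt, params.chem, k25_frozen=opts.k25_frozen
            )
            me = step_active(state_old.mech[f], lam, ch, dt, params.active)
        except Exception as err:
            raise type(err)(f"fiber {f}: {err}") from err
        chem_new.append(ch)
        mech_new.append(me)
        lam0 = lam
    return chem_new, mech_new


def stress_resolved_diag(c1, c2, state_old, dt, params, frame, opts):
    """Diagonal PK2 at trial C = diag(c1, c2, 1) with internal variables
    re-solved from the committed history (complex-safe fast path)."""
    if opts.passive_only:
        return stress_diag_given_state(
            c1, c2, state_old.chem, state_old.mech, params, frame, True
        )
    chem_new, mech_new = _advance_state_diag(c1, c2, state_old, dt, params, frame, opts)
    return stress_diag_given_state(c1, c2, chem_new, mech_new, params, frame)


def csda_tangent(
    C: np.ndarray,
    state_old: MaterialState,
    dt: float,
    params: MaterialParams,
    frame: FiberFrame,
    opts: MaterialOptions = MaterialOptions(),
    h: float = CSDA_STEP,
) -> np.ndarray:
    """6x6 material tangent 2 dS/dC (Voigt) by complex-step differentiation.

    Each of the six symmetric C-perturbations is applied as +i*h on the
    paired off-diagonal entries (or the diagonal entry), the internal
    variables are re-solved, and the derivative is Im(S)/h.
    """
    C = np.asarray(C, dtype=float)
    tangent = np.zeros((6, 6))
    for col, (i, j) in enumerate(_VOIGT):
        dC = np.zeros((3, 3), dtype=complex)
        if i == j:
            dC[i, i] = 1j * h
        else:
            dC[i, j] = 0.5j * h
            dC[j, i] = 0.5j * h
        S = _stress_resolved(C + dC, state_old, dt, params, frame, opts)
        col_vals = [S[a, b].imag / h for (a, b) in _VOIGT]
        tangent[:, col] = col_vals
    return 2.0 * tangent


def fd_tangent(
    C: np.ndarray,
    state_old: MaterialState,
    dt: float,
    params: MaterialParams,
    frame: FiberFrame,
    opts: MaterialOptions = MaterialOptions(),
    h: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference counterpart of :func:`csda_tangent`
    (independent check used by the test suite)."""
    C = np.asarray(C, dtype=float)
    tangent = np.zeros((6, 6))
    for col, (i, j) in enumerate(_VOIGT):
        dC = np.zeros((3, 3))
        if i == j:
            dC[i, i] = h
        else:
            dC[i, j] = 0.5 * h
            dC[j, i] = 0.5 * h
        Sp = _stress_resolved(C + dC, state_old, dt, params, frame, opts)
        Sm = _stress_resolved(C - dC, state_old, dt, params, frame, opts)
        col_vals = [(Sp[a, b] - Sm[a, b]).real / (2.0 * h) for (a, b) in _VOIGT]
        tangent[:, col] = col_vals
    return 2.0 * tangent
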