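"""Pressure protocols (staircase, heartbeat-like waves) and scenario
variants, producing diameter and state time series on the ring.

Two canonical protocols:

* staircase -- 600 s preconditioning at 10 mmHg, then 300 s holds at
  levels rising in 20 mmHg increments to 120 mmHg (the intermediate
  levels are a package default: only the preconditioning, hold time and
  final level are fixed by the experimental description);
* waves -- 2000 s at 80 mmHg, then 1 Hz raised-cosine waves at 120/80
  mmHg, stepped up to 180/120 mmHg and back down.

Pressure jumps between constant levels are ramped linearly over a short
configurable ramp window (default 1 s) for solver robustness.

Scenario modes mirror the experimental setups: fully active, Rho-kinase
inhibited (Y27632, MLCP activity k25 frozen), passive (zero calcium),
the adjusted-active variant (calcium inflow and target scaled to 75%),
and the two model reductions used to probe the Bayliss signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SolverError
from .material_point import MaterialOptions
from .params import MaterialParams
from .ring import RingConfiguration, RingMesh, RingSolution, closing_map, solve_step

MMHG_TO_KPA = 0.133322

K25_CONST_Y27632 = 0.892345  # 1/s, fitted frozen MLCP activity under Y27632
K25_CONST_REDUCED = 0.03  # 1/s, model reduction without MLCP mechanism
CA_CONST_REDUCED = 0.25  # uM, model reduction without any stretch sensing


@dataclass(frozen=True)
class Segment:
    """One protocol segment: a constant hold or a wave train."""

    duration: float  # s
    dt: float  # s, time-step during this segment
    kind: str = "constant"  # 'constant' | 'wave'
    p: float = 0.0  # mmHg (constant)
    p_dias: float = 0.0  # mmHg (wave)
    p_sys: float = 0.0  # mmHg (wave)
    freq: float = 1.0  # 1/s (wave)

    def __post_init__(self):
        if self.duration <= 0.0 or self.dt <= 0.0:
            raise ParameterError("segment duration and dt must be positive")
        if self.kind not in ("constant", "wave"):
            raise ParameterError(f"unknown segment kind {self.kind!r}")
        if min(self.p, self.p_dias, self.p_sys) < 0.0:
            raise ParameterError("pressures must be non-negative")


@dataclass(frozen=True)
class PressureProtocol:
    """Piecewise time -> pressure map built from ordered segments."""

    segments: tuple[Segment, ...]
    ramp: float = 1.0  # s, linear ramp at constant-level changes
    dt_ramp: float = 0.2  # s, sub-step during ramps
    name: str = ""

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def _segment_at(self, t: float):
        t0 = 0.0
        p_prev = 0.0  # unpressurized before the protocol starts
        for seg in self.segments:
            if t <= t0 + seg.duration or seg is self.segments[-1]:
                return seg, t0, p_prev
            t0 += seg.duration
            p_prev = self._end_pressure(seg)
        raise AssertionError("unreachable")

    @staticmethod
    def _end_pressure(seg: Segment) -> float:
        return seg.p if seg.kind == "constant" else seg.p_dias

    def pressure(self, t: float) -> float:
        """Pressure in mmHg at time t (t=0 is the protocol start)."""
        seg, t0, p_prev = self._segment_at(t)
        tau = t - t0
        if seg.kind == "constant":
            ramp = min(self.ramp, seg.duration)
            if tau < ramp and ramp > 0.0 and seg.p != p_prev:
                return p_prev + (seg.p - p_prev) * tau / ramp
            return seg.p
        return seg.p_dias + (seg.p_sys - seg.p_dias) * 0.5 * (1.0 - math.cos(2.0 * math.pi * seg.freq * tau))

    def pressure_kpa(self, t: float) -> float:
        return self.pressure(t) * MMHG_TO_KPA

    def time_grid(self) -> np.ndarray:
        """Strictly increasing solver time grid over the protocol."""
        times: list[float] = []
        t0 = 0.0
        p_prev = 0.0
        for seg in self.segments:
            if seg.kind == "constant" and seg.p != p_prev:
                ramp = min(self.ramp, seg.duration)
                n_sub = max(1, int(round(ramp / self.dt_ramp)))
                times.extend(t0 + ramp * (i + 1) / n_sub for i in range(n_sub))
                start = ramp
            else:
                start = 0.0
            n = max(1, int(math.ceil((seg.duration - start) / seg.dt - 1e-9)))
            times.extend(t0 + start + (seg.duration - start) * (i + 1) / n for i in range(n))
            t0 += seg.duration
            p_prev = self._end_pressure(seg)
        grid = np.unique(np.round(np.asarray(times), 9))
        return grid[grid > 0.0]


def build_staircase(
    levels: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0),
    hold: float = 300.0,
    pre_hold: float = 600.0,
    pre_pressure: float = 10.0,
    dt: float = 1.0,
    ramp: float = 1.0,
    dt_ramp: float = 0.2,
) -> PressureProtocol:
    """Pressure staircase: preconditioning hold then rising pressure steps."""
    segments = [Segment(duration=pre_hold, dt=dt, kind="constant", p=pre_pressure)]
    segments += [Segment(duration=hold, dt=dt, kind="constant", p=lvl) for lvl in levels]
    return PressureProtocol(
        segments=tuple(segments), ramp=ramp, dt_ramp=dt_ramp, name="staircase"
    )


def build_wave_protocol(
    pre_hold: float = 2000.0,
    pre_pressure: float = 80.0,
    span_low1: float = 1000.0,
    span_high: float = 400.0,
    span_low2: float = 800.0,
    low: tuple[float, float] = (80.0, 120.0),
    high: tuple[float, float] = (120.0, 180.0),
    freq: float = 1.0,
    dt_hold: float = 1.0,
    dt_wave: float = 0.02,
) -> PressureProtocol:
    """Heartbeat-like protocol: hold, then 1 Hz raised-cosine pressure
    waves at diastolic/systolic 80/120, stepped to 120/180 and back."""
    segs = (
        Segment(duration=pre_hold, dt=dt_hold, kind="constant", p=pre_pressure),
        Segment(duration=span_low1, dt=dt_wave, kind="wave", p_dias=low[0], p_sys=low[1], freq=freq),
        Segment(duration=span_high, dt=dt_wave, kind="wave", p_dias=high[0], p_sys=high[1], freq=freq),
        Segment(duration=span_low2, dt=dt_wave, kind="wave", p_dias=low[0], p_sys=low[1], freq=freq),
    )
    return PressureProtocol(segments=segs, name="waves")


# ------------------------------------------------------------ scenarios


@dataclass(frozen=True)
class ScenarioSpec:
    """Which parts of the chemo-mechanical machinery are active."""

    mode: str = "fully_active"
    k25_const: float | None = None
    ca_scale: float = 1.0
    ca_const: float | None = None

    _MODES = (
        "fully_active",
        "y27632_k25_const",
        "passive",
        "adjusted_active",
        "reduced_no_mlcp",
        "reduced_no_stretch",
    )

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ParameterError(f"unknown scenario mode {self.mode!r}")

    # -- factories ---------------------------------------------------
    @classmethod
    def fully_active(cls):
        return cls(mode="fully_active")

    @classmethod
    def y27632(cls, k25_const: float = K25_CONST_Y27632):
        return cls(mode="y27632_k25_const", k25_const=k25_const)

    @classmethod
    def passive(cls):
        return cls(mode="passive")

    @classmethod
    def adjusted_active(cls, ca_scale: float = 0.75):
        return cls(mode="adjusted_active", ca_scale=ca_scale)

    @classmethod
    def reduced_no_mlcp(cls, k25_const: float = K25_CONST_REDUCED):
        return cls(mode="reduced_no_mlcp", k25_const=k25_const)

    @classmethod
    def reduced_no_stretch(
        cls, k25_const: float = K25_CONST_REDUCED, ca_const: float = CA_CONST_REDUCED
    ):
        return cls(mode="reduced_no_stretch", k25_const=k25_const, ca_const=ca_const)

    # ----------------------------------------------------------------
    def apply(self, params: MaterialParams):
        """Resolve the scenario into (params, MaterialOptions, k25_init)."""
        if self.mode == "passive":
            return params, MaterialOptions(passive_only=True), None
        if self.mode == "fully_active":
            return params, MaterialOptions(), None
        if self.mode == "adjusted_active":
            p = params.replace_chem(
                gamma1=params.chem.gamma1 * self.ca_scale,
                gamma3=params.chem.gamma3 * self.ca_scale,
            )
            return p, MaterialOptions(), None
        if self.mode in ("y27632_k25_const", "reduced_no_mlcp"):
            return params, MaterialOptions(k25_frozen=True), self.k25_const
        if self.mode == "reduced_no_stretch":
            p = params.replace_chem(ca_const=self.ca_const)
            return p, MaterialOptions(k25_frozen=True), self.k25_const
        raise AssertionError("unreachable")

    def provenance(self) -> dict:
        return {
            "mode": self.mode,
            "k25_const": self.k25_const,
            "ca_scale": self.ca_scale,
            "ca_const": self.ca_const,
        }


# --------------------------------------------------------------- runner


@dataclass
class SimulationResult:
    """Time series of a scenario run plus the final converged solution."""

    t: np.ndarray  # s
    p_mmHg: np.ndarray
    d_outer: np.ndarray  # um
    outer_point: dict[str, np.ndarray]  # diagnostics at the outermost QP
    sigma_tt_profile: np.ndarray  # (n_steps, n_qp) circumferential Cauchy stress
    final: RingSolution
    scenario: ScenarioSpec
    protocol: PressureProtocol

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t_s": self.t, "p_mmHg": self.p_mmHg, "d_outer_um": self.d_outer}
        for key, arr in self.outer_point.items():
            data[f"outer_{key}"] = arr
        return pd.DataFrame(data)

    def profile_dataframe(self) -> pd.DataFrame:
        prof = self.final.stress_profile()
        df = pd.DataFrame(prof)
        for key in ("nC", "lam_a", "lam_e", "k25", "ca"):
            df[key] = [
                self.final.qp_diagnostics(i)[key if key != "nC" else "nC"]
                for i in range(self.final.mesh.n_qp)
            ]
        return df


_DIAG_KEYS = ("lam", "lam_a", "lam_e", "nA", "nB", "nC", "nD", "k25", "ca", "k16", "P_a", "P_c")


def run_scenario(
    ring: RingConfiguration,
    protocol: PressureProtocol,
    scenario: ScenarioSpec,
    params: MaterialParams | None = None,
    max_halvings: int = 5,
    log=None,
) -> SimulationResult:
    """Step the ring through a pressure protocol under a scenario.

    The residual-stress closing (opening-angle map) is solved first at
    zero pressure with frozen internal variables, then the protocol is
    stepped; any non-converged step is retried with recursive time-step
    halving (up to ``max_halvings``).
    """
    params = params or MaterialParams()
    eff_params, opts, k25_init = scenario.apply(params)
    mesh = RingMesh(ring)
    states = mesh.initial_states(eff_params, k25_init=k25_init)

    # close the opened sector at zero pressure (elastic; no history evolution)
    close_opts = MaterialOptions(passive_only=True)
    sol = solve_step(mesh, closing_map(ring), states, 0.0, dt=1.0, params=eff_params, opts=close_opts)
    r = sol.r_nodes
    states = sol.states

    grid = protocol.time_grid()
    n_steps = len(grid)
    t_rec = np.empty(n_steps)
    p_rec = np.empty(n_steps)
    d_rec = np.empty(n_steps)
    diag_rec = {k: np.empty(n_steps) for k in _DIAG_KEYS}
    prof_rec = np.empty((n_steps, mesh.n_qp))

    def advance(t0, t1, r, states, depth, jac=None):
        p_kpa = protocol.pressure_kpa(t1)
        try:
            return solve_step(
                mesh, r, states, p_kpa, dt=t1 - t0, params=eff_params, opts=opts, time=t1,
                jac_reuse=jac,
            )
        except SolverError:
            if depth >= max_halvings:
                raise
            tm = 0.5 * (t0 + t1)
            mid = advance(t0, tm, r, states, depth + 1)
            return advance(tm, t1, mid.r_nodes, mid.states, depth + 1)

    t_prev = 0.0
    jac = None
    for i, t in enumerate(grid):
        sol = advance(t_prev, t, r, states, 0, jac=jac)
        jac = sol.jacobian
        r, states = sol.r_nodes, sol.states
        t_prev = t
        t_rec[i] = t
        p_rec[i] = protocol.pressure(t)
        d_rec[i] = sol.d_outer
        prof_rec[i] = sol.stress_profile()["sigma_tt"]
        if opts.passive_only:
            for k in _DIAG_KEYS:
                diag_rec[k][i] = np.nan
        else:
            diag = sol.qp_diagnostics(mesh.n_qp - 1, fiber=0)
            for k in _DIAG_KEYS:
                diag_rec[k][i] = diag[k]
        if log is not None and i % 200 == 0:
            log(f"t={t:9.2f} s  p={p_rec[i]:7.2f} mmHg  d={d_rec[i]:8.3f} um  it={sol.iterations}")

    return SimulationResult(
        t=t_rec,
        p_mmHg=p_rec,
        d_outer=d_rec,
        outer_point=diag_rec,
        sigma_tt_profile=prof_rec,
        final=sol,
        scenario=scenario,
        protocol=protocol,
    )
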