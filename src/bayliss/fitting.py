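"""Two-stage parameter estimation against pressure-diameter traces.

The objective is the pooled relative diameter misfit

    z = sqrt( sum_k ((d_exp,k - d_sim,k) / d_exp,k)^2 )

over all supplied scenario traces.  Stage "passive" frees the five
passive parameters and the opening angle against a passive trace;
stage "active" frees the active-mechanical/chemical set (beta2 fixed)
plus the frozen MLCP rate of the Y27632 scenario, with the passive
block held at its stage-one values.

Experimental traces are not bundled (the published ones exist only as a
figure); a synthetic-trace generator built on the forward model is the
test bed, and a CSV import path serves users with digitized data.
Optimization uses a seeded differential-evolution global stage (the
population size mirrors the ~40 concurrent candidate sets used when the
reference parameters were produced) with optional local polish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .errors import FitError, ParameterError
from .params import MaterialParams
from .protocols import PressureProtocol, ScenarioSpec, run_scenario
from .ring import RingConfiguration, RingMesh, solve_equilibrium

PASSIVE_STAGE_PARAMS = ("alpha1", "alpha2", "alpha3", "alpha4", "alpha5", "phi")
ACTIVE_STAGE_PARAMS = (
    "eta",
    "gamma1",
    "lamc_rate_max",
    "lamc_rate_min",
    "k25_rate_max",
    "k25_rate_min",
    "lamp_rate_max",
    "lamp_rate_min",
    "mu_a",
    "kappa",
    "beta1",
    "k25_start",
    "k25_const",
)

_PASSIVE_FIELDS = {"alpha1", "alpha2", "alpha3", "alpha4", "alpha5"}
_ACTIVE_FIELDS = {"mu_a", "kappa", "beta1", "beta2"}


@dataclass(frozen=True)
class DiameterTrace:
    """Sampled outer-diameter time series for one scenario."""

    t: np.ndarray  # s
    d: np.ndarray  # um
    scenario: str = "passive"

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if t.ndim != 1 or t.shape != d.shape or len(t) == 0:
            raise ParameterError("trace needs matching, non-empty t and d arrays")
        if np.any(np.diff(t) <= 0.0):
            raise ParameterError("trace times must be strictly increasing")
        if np.any(d <= 0.0):
            raise ParameterError("diameters must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "d", d)

    @classmethod
    def from_csv(cls, path, scenario: str | None = None) -> "DiameterTrace":
        df = pd.read_csv(path)
        scen = scenario or (df["scenario"].iloc[0] if "scenario" in df else "passive")
        return cls(t=df["t_s"].to_numpy(), d=df["d_um"].to_numpy(), scenario=scen)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "d_um": self.d, "scenario": self.scenario}).to_csv(
            path, index=False
        )


def objective(traces_exp: list[DiameterTrace], traces_sim: list[DiameterTrace]) -> float:
    """Pooled relative-misfit objective z (dimensionless).

    Simulated traces are linearly interpolated onto the experimental
    time points; trace pairing follows list order.  Invariant to trace
    ordering/concatenation since the sum of squares is pooled.
    """
    if not traces_exp or len(traces_exp) != len(traces_sim):
        raise ParameterError("need equal, non-empty lists of traces")
    acc = 0.0
    for te, ts in zip(traces_exp, traces_sim):
        d_sim = np.interp(te.t, ts.t, ts.d)
        acc += float(np.sum(((te.d - d_sim) / te.d) ** 2))
    return float(np.sqrt(acc))


# ------------------------------------------------- forward evaluation


def _build_setup(base_params: MaterialParams, ring: RingConfiguration, values: dict):
    """Apply named free-parameter values onto the parameter blocks/ring."""
    passive_kw = {k: v for k, v in values.items() if k in _PASSIVE_FIELDS}
    active_kw = {k: v for k, v in values.items() if k in _ACTIVE_FIELDS}
    known = _PASSIVE_FIELDS | _ACTIVE_FIELDS | {"phi", "k25_const"}
    chem_kw = {k: v for k, v in values.items() if k not in known}
    p = base_params
    if passive_kw:
        p = p.replace_passive(**passive_kw)
    if active_kw:
        p = p.replace_active(**active_kw)
    if chem_kw:
        p = p.replace_chem(**chem_kw)
    if "phi" in values:
        ring = replace(ring, phi_deg=values["phi"])
    return p, ring


def simulate_passive_trace(
    ring: RingConfiguration,
    protocol: PressureProtocol,
    params: MaterialParams,
    sample_t: np.ndarray,
) -> DiameterTrace:
    """Fast passive forward model: the passive response is elastic, so
    the diameter at each sample time is a static equilibrium at the
    protocol pressure (with pressure continuation along sorted levels)."""
    sample_t = np.asarray(sample_t, dtype=float)
    pressures = np.array([protocol.pressure_kpa(t) for t in sample_t])
    unique_p = np.unique(pressures)
    mesh = RingMesh(ring)
    states = mesh.initial_states(params)
    d_at = {}
    sol = None
    p_prev = 0.0
    for p in unique_p:  # ascending: each solve continues from the previous
        sol = solve_equilibrium(
            ring,
            p,
            params,
            mesh=mesh,
            states=states,
            r_guess=None if sol is None else sol.r_nodes,
            n_continuation=4 if sol is None else max(1, int(abs(p - p_prev) / 1.0) + 1),
            p_start=0.0 if sol is None else p_prev,
        )
        d_at[p] = sol.d_outer
        p_prev = p
    d = np.array([d_at[p] for p in pressures])
    return DiameterTrace(t=sample_t, d=d, scenario="passive")


def forward_trace(
    ring: RingConfiguration,
    protocol: PressureProtocol,
    scenario: ScenarioSpec,
    params: MaterialParams,
    sample_t: np.ndarray | None = None,
) -> DiameterTrace:
    """Forward-model diameter trace for any scenario."""
    if scenario.mode == "passive":
        if sample_t is None:
            sample_t = protocol.time_grid()
        return simulate_passive_trace(ring, protocol, params, sample_t)
    result = run_scenario(ring, protocol, scenario, params)
    t, d = result.t, result.d_outer
    if sample_t is not None:
        d = np.interp(sample_t, t, d)
        t = np.asarray(sample_t, dtype=float)
    return DiameterTrace(t=t, d=d, scenario=scenario.mode)


def generate_synthetic_trace(
    ring: RingConfiguration,
    protocol: PressureProtocol,
    scenario: ScenarioSpec,
    params: MaterialParams,
    noise_sd_rel: float = 0.0,
    seed: int = 0,
    sample_t: np.ndarray | None = None,
) -> DiameterTrace:
    """Forward-model trace with multiplicative Gaussian noise of the
    given relative standard deviation (seed-deterministic)."""
    clean = forward_trace(ring, protocol, scenario, params, sample_t=sample_t)
    if noise_sd_rel == 0.0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = clean.d * (1.0 + noise_sd_rel * rng.standard_normal(len(clean.d)))
    return DiameterTrace(t=clean.t, d=noisy, scenario=clean.scenario)


# ----------------------------------------------------------- fitting


@dataclass
class FitSpec:
    """Specification of one fitting stage."""

    stage: str  # 'passive' | 'active'
    free: dict[str, tuple[float, float]]  # name -> (lo, hi)
    traces: list[DiameterTrace]
    ring: RingConfiguration
    protocol: PressureProtocol
    base_params: MaterialParams = field(default_factory=MaterialParams)
    fixed: dict[str, float] = field(default_factory=dict)
    popsize: int = 40
    maxiter: int = 50
    tol: float = 1e-8
    seed: int = 0
    polish: bool = True

    def __post_init__(self):
        if self.stage not in ("passive", "active"):
            raise ParameterError("stage must be 'passive' or 'active'")
        allowed = set(PASSIVE_STAGE_PARAMS if self.stage == "passive" else ACTIVE_STAGE_PARAMS)
        unknown = set(self.free) - allowed
        if unknown:
            raise ParameterError(f"free parameters {sorted(unknown)} not in stage {self.stage}")
        if not self.traces:
            raise ParameterError("at least one trace is required")


@dataclass
class FitResult:
    params: dict[str, float]
    z: float
    nfev: int
    success: bool
    message: str
    history: list[float]


def _scenario_for(label: str, values: dict) -> ScenarioSpec:
    if label == "passive":
        return ScenarioSpec.passive()
    if label == "fully_active":
        return ScenarioSpec.fully_active()
    if label == "y27632_k25_const":
        k25 = values.get("k25_const")
        return ScenarioSpec.y27632() if k25 is None else ScenarioSpec.y27632(k25_const=k25)
    raise ParameterError(f"no scenario for trace label {label!r}")


def fit(spec: FitSpec) -> FitResult:
    """Minimize the pooled objective over the free parameters."""
    names = list(spec.free.keys())
    bounds = [spec.free[n] for n in names]
    history: list[float] = []
    failures: list[str] = []

    def evaluate(x) -> float:
        values = dict(spec.fixed)
        values.update({n: float(v) for n, v in zip(names, x)})
        try:
            params, ring = _build_setup(spec.base_params, spec.ring, values)
            sims = []
            for trace in spec.traces:
                scen = _scenario_for(trace.scenario, values)
                sims.append(forward_trace(ring, spec.protocol, scen, params, sample_t=trace.t))
            z = objective(spec.traces, sims)
        except Exception as err:  # noqa: BLE001 - any forward failure penalized
            failures.append(f"{values}: {err}")
            return 1e6
        history.append(z)
        return z

    # degenerate point bounds: no optimization needed
    if all(lo == hi for lo, hi in bounds):
        x0 = np.array([lo for lo, _ in bounds])
        z = evaluate(x0)
        if z >= 1e6:
            raise FitError("forward model failed at the fixed point; log:\n" + "\n".join(failures))
        return FitResult(
            params=dict(zip(names, x0)), z=z, nfev=1, success=True, message="point bounds", history=history
        )

    res = differential_evolution(
        evaluate,
        bounds=bounds,
        seed=spec.seed,
        popsize=spec.popsize,
        maxiter=spec.maxiter,
        tol=spec.tol,
        polish=spec.polish,
        init="sobol",
        updating="immediate",
        workers=1,
    )
    if len(history) == 0 or (res.fun >= 1e6):
        raise FitError(
            "all forward evaluations failed; per-candidate log:\n" + "\n".join(failures[:50])
        )
    return FitResult(
        params=dict(zip(names, [float(v) for v in res.x])),
        z=float(res.fun),
        nfev=int(res.nfev),
        success=bool(res.success),
        message=str(res.message),
        history=history,
    )
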