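"""Material parameter blocks.

Defaults are the optimized values for a rat middle cerebral artery:
the passive block describes the elastin matrix and collagen fibers,
the chemical block the four-state cross-bridge kinetics with its
stretch-dependent MLCK (calcium) and MLCP regulation, and the active
block the smooth-muscle stiffness and the Hill-type contraction law.

Units are fixed globally: seconds, micromolar (calcium), kPa
(stresses/energies), dimensionless stretches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

from .errors import ParameterError


def sigmoid_zero_offset(rate_min: float, rate_max: float, gamma: float) -> float:
    """Offset tau making the four-parameter sigmoid

        r(x) = rate_min + (rate_max - rate_min) / (1 + exp(gamma*(x - tau)))

    vanish exactly at x = 0, i.e. tau = ln((rate_min - rate_max)/rate_min - 1)
    / (-gamma).  Requires rate_min < 0 < rate_max.
    """
    if rate_min == rate_max:
        # degenerate sigmoid: constant rate, no offset needed
        return 0.0
    if not (rate_min < 0.0 < rate_max):
        raise ParameterError(
            f"sigmoid rate bounds must straddle zero, got [{rate_min}, {rate_max}]"
        )
    arg = (rate_min - rate_max) / rate_min - 1.0
    if arg <= 0.0:
        raise ParameterError("invalid sigmoid bounds: log of non-positive argument")
    return math.log(arg) / (-gamma)


@dataclass(frozen=True)
class PassiveParams:
    """Polyconvex passive model: neo-Hookean matrix + volumetric penalty
    + fiber term alpha4 <K3 - 2>^alpha5."""

    alpha1: float = 11.52507  # kPa
    alpha2: float = 151.73775  # kPa
    alpha3: float = 2.75662
    alpha4: float = 1.27631  # kPa
    alpha5: float = 3.08798

    def __post_init__(self):
        bad = []
        if not self.alpha1 > 0:
            bad.append("alpha1 > 0")
        if not self.alpha2 > 0:
            bad.append("alpha2 > 0")
        if not self.alpha3 > 1:
            bad.append("alpha3 > 1")
        if not self.alpha4 > 0:
            bad.append("alpha4 > 0")
        if not self.alpha5 > 2:
            bad.append("alpha5 > 2")
        if bad:
            raise ParameterError("passive parameter restrictions violated: " + ", ".join(bad))


@dataclass(frozen=True)
class ChemParams:
    """Cross-bridge kinetics and stretch-sensing parameters.

    k1 = k6 (MLCK, calcium-dependent) and k2 = k5 (MLCP) are state
    dependent; k3, k4, k7 are constant.  The reference stretches
    lam_c_bar and lam_p_bar and the MLCP rate k25 evolve by bounded
    sigmoid laws whose offsets tau_* are constructed so each rate is
    exactly zero when its driving difference vanishes.
    """

    # constant reaction rates (1/s)
    k3: float = 0.134
    k4: float = 0.00166
    k7: float = 0.000066
    # MLCK activation
    eta: float = 0.1624  # 1/s, max k_{1/6}
    ca50: float = 0.4  # uM
    # stretch-dependent calcium
    gamma1: float = 0.5131  # uM
    gamma2: float = 50.0  # 1/uM
    gamma3: float = 0.9  # uM
    lambda50_c: float = 1.2
    lamc_rate_min: float = -0.0443  # 1/s
    lamc_rate_max: float = 0.0443  # 1/s
    # MLCP activity evolution
    gamma4: float = 200.0
    zeta1: float = 100.0  # s
    k25_rate_min: float = -0.0010694  # 1/s^2
    k25_rate_max: float = 0.0009735  # 1/s^2
    # MLCP reference stretch evolution
    gamma5: float = 50.0  # s
    zeta2: float = 1000.0
    delta_lamp_min: float = -0.00001
    lamp_rate_min: float = -0.0002323  # 1/s
    lamp_rate_max: float = 0.0000699  # 1/s
    gamma6: float = 1.5  # 1/s
    lambda50_p: float = 1.0
    # start values of the evolving quantities
    k25_start: float = 1.82758  # 1/s
    lamc_start: float = 1.0
    lamp_start: float = 1.0
    # optional override: constant calcium (uM); None = stretch-dependent
    ca_const: float | None = None

    def __post_init__(self):
        if self.ca50 <= 0:
            raise ParameterError("ca50 must be positive")
        if self.lambda50_p <= 0:
            raise ParameterError("lambda50_p must be positive")
        for k in ("k3", "k4", "k7"):
            if getattr(self, k) < 0:
                raise ParameterError(f"reaction rate {k} must be non-negative")
        # compute (and thereby validate) the tau offsets once
        object.__setattr__(
            self, "tau_c", sigmoid_zero_offset(self.lamc_rate_min, self.lamc_rate_max, self.gamma2)
        )
        object.__setattr__(
            self, "tau_p", sigmoid_zero_offset(self.k25_rate_min, self.k25_rate_max, self.gamma4)
        )
        object.__setattr__(
            self, "tau_k", sigmoid_zero_offset(self.lamp_rate_min, self.lamp_rate_max, self.gamma5)
        )


@dataclass(frozen=True)
class ActiveParams:
    """Active mechanical parameters: smooth-muscle stiffness mu_a, maximal
    driving stress kappa, and the Hill-type rate constants beta1, beta2."""

    mu_a: float = 11.857  # kPa
    kappa: float = 148.262  # kPa
    beta1: float = 0.001006  # 1/s
    beta2: float = 26.68  # kPa
    lam_a_start: float = 1.0

    def __post_init__(self):
        for name in ("mu_a", "kappa", "beta1", "beta2", "lam_a_start"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class MaterialParams:
    """All parameter blocks bundled."""

    passive: PassiveParams = field(default_factory=PassiveParams)
    chem: ChemParams = field(default_factory=ChemParams)
    active: ActiveParams = field(default_factory=ActiveParams)

    def replace_chem(self, **kw) -> "MaterialParams":
        return replace(self, chem=replace(self.chem, **kw))

    def replace_active(self, **kw) -> "MaterialParams":
        return replace(self, active=replace(self.active, **kw))

    def replace_passive(self, **kw) -> "MaterialParams":
        return replace(self, passive=replace(self.passive, **kw))


def params_to_dict(p: MaterialParams) -> dict:
    out = {}
    for block_name in ("passive", "chem", "active"):
        block = getattr(p, block_name)
        out[block_name] = {f.name: getattr(block, f.name) for f in fields(block)}
    return out


def params_from_dict(d: dict) -> MaterialParams:
    return MaterialParams(
        passive=PassiveParams(**d.get("passive", {})),
        chem=ChemParams(**d.get("chem", {})),
        active=ActiveParams(**d.get("active", {})),
    )
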