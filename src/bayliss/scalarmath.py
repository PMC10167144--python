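"""Scalar helpers that are safe for both real and complex arguments.

The consistent tangent moduli are computed by complex-step derivative
approximation (CSDA), which requires every scalar function on the
constitutive path -- including branch decisions such as Macaulay
brackets -- to accept complex perturbations of the form x + i*h with
h ~ 1e-20.  Branches are therefore decided on the real part, and
exponentials are capped to keep intermediate values finite without
affecting any physically reachable regime.
"""

from __future__ import annotations

import cmath
import math

# exp cap: e^300 ~ 2e130 stays finite through every downstream product;
# all model sigmoids saturate far below this argument.
_EXP_CAP = 300.0


def sexp(x):
    """exp(x) for float or complex x, with the real part capped."""
    if isinstance(x, complex):
        if x.real > _EXP_CAP:
            x = complex(_EXP_CAP, x.imag)
        return cmath.exp(x)
    return math.exp(min(x, _EXP_CAP))


def ssqrt(x):
    """Principal square root for float or complex x."""
    if isinstance(x, complex):
        return cmath.sqrt(x)
    return math.sqrt(x)


def slog(x):
    if isinstance(x, complex):
        return cmath.log(x)
    return math.log(x)


def spow(x, a):
    """x**a with the branch decided on the real part (x.real > 0 assumed)."""
    if isinstance(x, complex):
        return cmath.exp(a * cmath.log(x))
    return x**a


def macaulay(x):
    """Positive part <x> = (x + |x|)/2, complex-step safe.

    For complex arguments the branch is taken on the real part so the
    derivative information in the imaginary part survives on the active
    branch and is zeroed on the inactive one.
    """
    return x if x.real > 0.0 else 0.0 * x


def inv_logistic(x):
    """1 / (1 + exp(x)), overflow-safe for float and complex x."""
    if x.real > 0.0:
        e = sexp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + sexp(x))


def is_complex(*vals) -> bool:
    return any(isinstance(v, complex) for v in vals)
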