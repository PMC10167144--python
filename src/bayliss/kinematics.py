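"""Deformation measures, structural tensors and invariants for a
fiber-reinforced continuum.

Fibers are stored as reference-configuration unit vectors in a local
cylindrical basis (radial, circumferential, axial).  The fiber angle
beta is measured from the circumferential toward the axial direction;
both mirror-symmetric families +/-beta are always instantiated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidDeformationError
from .scalarmath import ssqrt

_UNIT_TOL = 1e-12


@dataclass(frozen=True)
class FiberFrame:
    """Two helical fiber families given by unit direction vectors.

    ``directions`` is a (2, 3) array in the local (radial,
    circumferential, axial) basis; ``angle_beta`` holds the angle of
    each family to the circumferential direction in degrees.
    """

    directions: np.ndarray
    angle_beta: tuple[float, float]

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        if d.shape != (2, 3):
            raise ValueError("directions must be a (2, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError(f"fiber directions must be unit vectors, norms={norms}")
        object.__setattr__(self, "directions", d)
        # squared components, used by the diagonal-deformation fast path
        object.__setattr__(
            self,
            "m_diag",
            [(float(a[0] ** 2), float(a[1] ** 2), float(a[2] ** 2)) for a in d],
        )

    @classmethod
    def from_beta(cls, beta_deg: float) -> "FiberFrame":
        """Build the mirror-symmetric pair +/-beta in the theta-z plane."""
        b = np.deg2rad(beta_deg)
        d = np.array(
            [
                [0.0, np.cos(b), np.sin(b)],
                [0.0, np.cos(b), -np.sin(b)],
            ]
        )
        return cls(directions=d, angle_beta=(beta_deg, -beta_deg))

    def structural_tensors(self) -> list[np.ndarray]:
        return [np.outer(a, a) for a in self.directions]


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient F and right Cauchy-Green tensor C = F^T F."""

    F: np.ndarray
    C: np.ndarray

    @classmethod
    def from_F(cls, F: np.ndarray) -> "DeformationState":
        F = np.asarray(F)
        if np.isrealobj(F) and np.linalg.det(F).real <= 0.0:
            raise InvalidDeformationError("det F must be positive")
        return cls(F=F, C=F.T @ F)


@dataclass(frozen=True)
class InvariantSet:
    """Principal invariants I1..I3, mixed invariants I4, I5 per fiber and
    the polyconvex combination K3 = I1*I4 - I5 per fiber."""

    I1: float
    I2: float
    I3: float
    I4: tuple
    I5: tuple
    K3: tuple


def _check_spd(C: np.ndarray) -> None:
    if not np.isrealobj(C):
        return  # complex-step evaluation path: admissibility was checked on the real point
    if not np.allclose(C, C.T, atol=1e-10):
        raise InvalidDeformationError("C must be symmetric")
    ev = np.linalg.eigvalsh(C)
    if np.any(ev <= 0.0):
        raise InvalidDeformationError(f"C must be positive definite, eigenvalues {ev}")


def compute_invariants(C: np.ndarray, frame: FiberFrame, check: bool = True) -> InvariantSet:
    """All invariants of C for the two fiber families of ``frame``."""
    C = np.asarray(C)
    if check:
        _check_spd(C)
    I1 = np.trace(C)
    C2 = C @ C
    I2 = 0.5 * (I1 * I1 - np.trace(C2))
    I3 = np.linalg.det(C)
    I4, I5, K3 = [], [], []
    for a in frame.directions:
        i4 = a @ C @ a
        i5 = a @ C2 @ a
        I4.append(i4)
        I5.append(i5)
        K3.append(I1 * i4 - i5)
    return InvariantSet(I1=I1, I2=I2, I3=I3, I4=tuple(I4), I5=tuple(I5), K3=tuple(K3))


def fiber_stretch(C: np.ndarray, direction: np.ndarray):
    """Stretch lambda = sqrt(a . C . a) along a unit fiber direction."""
    i4 = direction @ np.asarray(C) @ direction
    if i4.real <= 0.0:
        raise InvalidDeformationError("fiber invariant I4 must be positive")
    return ssqrt(complex(i4)) if np.iscomplexobj(C) else float(np.sqrt(i4))
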