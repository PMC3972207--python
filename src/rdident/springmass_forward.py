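"""Closed-form time-harmonic forward solutions for the spring-mass analogy.

The elastography analogue is a chain of interior masses connected by springs,
displacement-driven at both ends with amplitude ``u0`` (applied forces are
unknown in elastography, so only motion data is available).  The single-mass
reduction — one mass between two identical springs — has amplitude

    U = 2 k u0 / (2 k - omega^2 m),

with complex stiffness k and complex mass m.  Axial (longitudinal) and
transverse (shear) vibration are treated as independent scalar modes with the
same topology but their own complex stiffness; the mass is shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .rd_model import RDSpringMaterial

__all__ = [
    "ResonanceError",
    "HarmonicDrive",
    "ComplexMeasurement",
    "RESONANCE_RTOL",
    "transfer_single_mode",
    "solve_chain",
    "axial_stiffness_case3",
    "axial_stiffness_case4",
    "axial_stiffness_case5",
    "forward_case3",
    "forward_case4",
    "forward_case5",
]

#: |2 k - omega^2 m| below this fraction of |2 k| counts as resonant.
RESONANCE_RTOL = 1e-10

Mode = Literal["axial", "transverse"]


class ResonanceError(ArithmeticError):
    """The drive frequency sits on an (undamped) resonance of the system."""


@dataclass(frozen=True)
class HarmonicDrive:
    """Boundary drive: both chain ends displaced by ``u0 e^{+i omega t}``."""

    omega: float
    u0: float = 1.0
    mode: Mode = "transverse"

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if self.u0 == 0:
            raise ValueError("drive amplitude u0 must be nonzero")


@dataclass(frozen=True)
class ComplexMeasurement:
    """A complex displacement amplitude of one interior mass."""

    mode: Mode
    omega: float
    u0: float
    value: complex
    mass_index: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("measurement value must be finite")
        if self.mass_index not in (1, 2, 3):
            raise ValueError(f"mass_index must be 1..3, got {self.mass_index}")


def transfer_single_mode(k_mode: complex, m: complex, omega: float, u0: float) -> complex:
    """Interior-mass amplitude U = 2 k u0 / (2 k - omega^2 m).

    Raises :class:`ResonanceError` when the denominator falls below
    ``RESONANCE_RTOL * |2 k|`` (undamped resonance omega^2 = 2 kR / mR).
    """
    num = 2.0 * k_mode * u0
    den = 2.0 * k_mode - omega**2 * m
    if abs(den) < RESONANCE_RTOL * abs(2.0 * k_mode):
        raise ResonanceError(
            f"drive frequency omega={omega} is resonant: |2k - w^2 m| = {abs(den):.3e}"
        )
    return num / den


def solve_chain(
    materials: Sequence[RDSpringMaterial],
    drive: HarmonicDrive,
) -> list[ComplexMeasurement]:
    """Solve the three-mass, four-spring chain driven at both ends.

    ``materials`` holds one :class:`RDSpringMaterial` per interior mass
    (3 entries); spring j (j = 1..4) takes its complex stiffness from the
    adjacent material ``materials[min(j, 3) - 1]`` so a homogeneous list
    yields the homogeneous chain and stiffness steps can be placed between
    masses.  Interior equilibrium for mass j:

        k_j (u_{j-1} - u_j) + k_{j+1} (u_{j+1} - u_j) + omega^2 m_j u_j = 0,

    with u_0 = u_4 = u0.  The 3x3 complex tridiagonal system is solved
    exactly; a homogeneous chain gives u1 = u3 by mirror symmetry.
    """
    if len(materials) != 3:
        raise ValueError(f"chain requires 3 interior masses, got {len(materials)}")
    w2 = drive.omega**2
    ks = [materials[0].k, materials[0].k, materials[1].k, materials[2].k]
    # spring j couples mass j-1 to mass j: springs (k1..k4), masses (m1..m3)
    A = np.zeros((3, 3), dtype=complex)
    b = np.zeros(3, dtype=complex)
    for j in range(3):
        kl, kr = ks[j], ks[j + 1]
        A[j, j] = kl + kr - w2 * materials[j].m
        if j > 0:
            A[j, j - 1] = -kl
        if j < 2:
            A[j, j + 1] = -kr
    b[0] = ks[0] * drive.u0
    b[2] = ks[3] * drive.u0
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1.0 / RESONANCE_RTOL:
        raise ResonanceError(
            f"chain system is singular at omega={drive.omega} (cond={cond:.3e})"
        )
    u = np.linalg.solve(A, b)
    return [
        ComplexMeasurement(mode=drive.mode, omega=drive.omega, u0=drive.u0,
                           value=complex(u[j]), mass_index=j + 1)
        for j in range(3)
    ]


def axial_stiffness_case3(shear: RDSpringMaterial, Khat: float) -> complex:
    """Longitudinal stiffness (Khat + 4 kR / 3) + i (4 kI / 3): real bulk analogue."""
    return complex(Khat + 4.0 * shear.kR / 3.0, 4.0 * shear.kI / 3.0)


def axial_stiffness_case4(shear: RDSpringMaterial, a: float, b: float) -> complex:
    """Longitudinal stiffness a kR + i b kI with free proportionality factors."""
    if a <= 0:
        raise ValueError(f"factor a must be positive, got {a}")
    return complex(a * shear.kR, b * shear.kI)


def axial_stiffness_case5(shear: RDSpringMaterial, Khat: float, KI: float) -> complex:
    """Longitudinal stiffness (Khat + 4 kR / 3) + i (KI + 4 kI / 3)."""
    return complex(Khat + 4.0 * shear.kR / 3.0, KI + 4.0 * shear.kI / 3.0)


def _two_mode_forward(
    shear: RDSpringMaterial,
    k_axial: complex,
    drive_axial: HarmonicDrive,
    drive_transverse: HarmonicDrive,
) -> tuple[ComplexMeasurement, ComplexMeasurement]:
    ax = transfer_single_mode(k_axial, shear.m, drive_axial.omega, drive_axial.u0)
    tr = transfer_single_mode(shear.k, shear.m, drive_transverse.omega, drive_transverse.u0)
    return (
        ComplexMeasurement("axial", drive_axial.omega, drive_axial.u0, ax),
        ComplexMeasurement("transverse", drive_transverse.omega, drive_transverse.u0, tr),
    )


def forward_case3(
    shear: RDSpringMaterial,
    Khat: float,
    drive_axial: HarmonicDrive,
    drive_transverse: HarmonicDrive,
) -> tuple[ComplexMeasurement, ComplexMeasurement]:
    """Single-frequency axial + transverse response, real bulk stiffness Khat >> kR."""
    return _two_mode_forward(shear, axial_stiffness_case3(shear, Khat),
                             drive_axial, drive_transverse)


def forward_case4(
    shear: RDSpringMaterial,
    a: float,
    b: float,
    drive_axial: HarmonicDrive,
    drive_transverse: HarmonicDrive,
) -> tuple[ComplexMeasurement, ComplexMeasurement]:
    """Axial + transverse response with relative damping factors (a, b)."""
    return _two_mode_forward(shear, axial_stiffness_case4(shear, a, b),
                             drive_axial, drive_transverse)


def forward_case5(
    shear: RDSpringMaterial,
    Khat: float,
    KI: float,
    drive_axial: HarmonicDrive,
    drive_transverse: HarmonicDrive,
) -> tuple[ComplexMeasurement, ComplexMeasurement]:
    """Axial + transverse response with dilatational attenuation KI."""
    return _two_mode_forward(shear, axial_stiffness_case5(shear, Khat, KI),
                             drive_axial, drive_transverse)
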