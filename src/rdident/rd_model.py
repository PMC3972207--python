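"""Generalized time-harmonic Rayleigh damping (RD) material models.

In the time-harmonic setting (displacement ``u(t) = U e^{+i omega t}``) a
Rayleigh-damped structure with damping matrix ``C = alpha*M + beta*K`` is
equivalent to a complex stiffness ``k = kR (1 + i omega beta)`` and a complex
mass ``m = mR (1 - i alpha / omega)``.  The continuum analogue replaces
(k, m) by a complex shear modulus ``mu = muR + i muI`` and a complex density
``rho = rhoR + i rhoI``: the imaginary stiffness component models
viscoelastic (strain-rate) attenuation, the imaginary mass/density component
models attenuation proportional to local velocity, as if the solid matrix
moved through a stationary viscous fluid.

Under the package-wide ``e^{+i omega t}`` convention an admissible
(dissipative) material has ``kI >= 0`` (``muI >= 0``) and ``mI <= 0``
(``rhoI <= 0``); equivalently ``alpha >= 0`` and ``beta >= 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

__all__ = [
    "TIME_CONVENTION",
    "AdmissibilityError",
    "RDSpringMaterial",
    "ContinuumRDMaterial",
    "RayleighCoefficients",
    "to_rayleigh_coefficients",
    "from_rayleigh_coefficients",
    "damping_ratio",
    "damping_ratio_from_coefficients",
    "mode_damping_ratio",
    "p_wave_modulus",
    "rescale_frequency",
]

#: Fixed package-wide time convention: displacements vary as e^{+i omega t}.
#: Results for the opposite convention are the complex conjugates.
TIME_CONVENTION = "+iwt"


class AdmissibilityError(ValueError):
    """A material parameter set would inject rather than dissipate energy."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise AdmissibilityError(msg)


@dataclass(frozen=True)
class RDSpringMaterial:
    """Spring-mass analogue of an RD material.

    Parameters
    ----------
    kR, kI : float
        Real spring stiffness and its viscoelastic (imaginary) component.
    mR, mI : float
        Real mass and its inertial-damping (imaginary) component.
    allow_gain : bool
        Opt out of the dissipativity sign checks (``kI >= 0``, ``mI <= 0``)
        so that degenerate/ill-posed configurations can still be studied.
    """

    kR: float
    kI: float = 0.0
    mR: float = 1.0
    mI: float = 0.0
    allow_gain: bool = False

    def __post_init__(self) -> None:
        _require(self.kR > 0, f"real stiffness kR must be positive, got {self.kR}")
        _require(self.mR > 0, f"real mass mR must be positive, got {self.mR}")
        if not self.allow_gain:
            _require(self.kI >= 0, f"VE component kI={self.kI} < 0 injects energy "
                                   "under the e^{+iwt} convention")
            _require(self.mI <= 0, f"inertial component mI={self.mI} > 0 injects "
                                   "energy under the e^{+iwt} convention")

    @property
    def k(self) -> complex:
        """Complex stiffness kR + i kI."""
        return complex(self.kR, self.kI)

    @property
    def m(self) -> complex:
        """Complex mass mR + i mI."""
        return complex(self.mR, self.mI)

    @property
    def undamped_resonance(self) -> float:
        """omega at which the undamped single-mass denominator 2kR - w^2 mR vanishes."""
        return math.sqrt(2.0 * self.kR / self.mR)

    def complex_pair(self, convention: str = TIME_CONVENTION) -> tuple[complex, complex]:
        """(k, m) under the requested time convention ('+iwt' or '-iwt')."""
        if convention == TIME_CONVENTION:
            return self.k, self.m
        if convention == "-iwt":
            return self.k.conjugate(), self.m.conjugate()
        raise ValueError(f"unknown time convention {convention!r}")


@dataclass(frozen=True)
class ContinuumRDMaterial:
    """Continuum RD material: complex shear modulus, complex density, bulk modulus.

    ``K`` is the (storage) bulk modulus; soft tissue is nearly incompressible,
    K/muR >= ``incompressibility_ratio`` (default 1e4).  ``KI`` is the optional
    dilatational attenuation component.
    """

    muR: float
    muI: float = 0.0
    rhoR: float = 1000.0
    rhoI: float = 0.0
    K: float = 1.0e4
    KI: float | None = None
    allow_gain: bool = False
    incompressibility_ratio: float = 1.0e4

    def __post_init__(self) -> None:
        _require(self.muR > 0, f"shear storage modulus muR must be positive, got {self.muR}")
        _require(self.rhoR > 0, f"real density rhoR must be positive, got {self.rhoR}")
        _require(self.K > 0, f"bulk modulus K must be positive, got {self.K}")
        if not self.allow_gain:
            _require(self.muI >= 0, f"shear loss component muI={self.muI} < 0 injects "
                                    "energy under the e^{+iwt} convention")
            _require(self.rhoI <= 0, f"imaginary density rhoI={self.rhoI} > 0 injects "
                                     "energy under the e^{+iwt} convention")
            if self.KI is not None:
                _require(self.KI >= 0, f"dilatational loss KI={self.KI} < 0 injects energy")

    @property
    def mu(self) -> complex:
        return complex(self.muR, self.muI)

    @property
    def rho(self) -> complex:
        return complex(self.rhoR, self.rhoI)

    @property
    def nearly_incompressible(self) -> bool:
        return self.K / self.muR >= self.incompressibility_ratio


Material = Union[RDSpringMaterial, ContinuumRDMaterial]


@dataclass(frozen=True)
class RayleighCoefficients:
    """Classical Rayleigh damping coefficients of C = alpha*M + beta*K.

    alpha (1/s) weights the mass-proportional part, beta (s) the
    stiffness-proportional part; both are >= 0 for admissible materials.
    """

    alpha: float
    beta: float


def _stiffness_mass_view(mat: Material) -> tuple[float, float, float, float]:
    """(kR, kI, mR, mI)-like view of either material kind."""
    if isinstance(mat, RDSpringMaterial):
        return mat.kR, mat.kI, mat.mR, mat.mI
    if isinstance(mat, ContinuumRDMaterial):
        return mat.muR, mat.muI, mat.rhoR, mat.rhoI
    raise TypeError(f"unsupported material type {type(mat).__name__}")


def to_rayleigh_coefficients(mat: Material, omega: float) -> RayleighCoefficients:
    """Map the complex (stiffness, mass) pair at ``omega`` to (alpha, beta).

    Under e^{+iwt}: k = kR(1 + i omega beta) and m = mR(1 - i alpha/omega),
    hence beta = kI / (omega kR) and alpha = -omega mI / mR.
    """
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    kR, kI, mR, mI = _stiffness_mass_view(mat)
    return RayleighCoefficients(alpha=-omega * mI / mR, beta=kI / (omega * kR))


def from_rayleigh_coefficients(
    coeffs: RayleighCoefficients,
    omega: float,
    kR: float,
    mR: float,
    *,
    continuum: bool = False,
    **kwargs,
) -> Material:
    """Inverse of :func:`to_rayleigh_coefficients`: rebuild the complex material."""
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    kI = coeffs.beta * omega * kR
    mI = -coeffs.alpha * mR / omega
    if continuum:
        return ContinuumRDMaterial(muR=kR, muI=kI, rhoR=mR, rhoI=mI, **kwargs)
    return RDSpringMaterial(kR=kR, kI=kI, mR=mR, mI=mI, **kwargs)


def damping_ratio_from_coefficients(coeffs: RayleighCoefficients, omega: float) -> float:
    """xi = (alpha/omega + beta*omega) / 2."""
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    return 0.5 * (coeffs.alpha / omega + coeffs.beta * omega)


def damping_ratio(mat: Material, omega: float) -> float:
    """Dimensionless damping ratio xi of an RD material at ``omega``.

    Evaluates xi = (alpha/omega + beta*omega)/2 with (alpha, beta) taken from
    :func:`to_rayleigh_coefficients`; xi >= 0 for admissible materials and
    xi = 0 iff both imaginary components vanish.
    """
    return damping_ratio_from_coefficients(to_rayleigh_coefficients(mat, omega), omega)


def mode_damping_ratio(k_mode: complex) -> float:
    """Viscoelastic loss ratio Im(k)/Re(k) of a single propagation mode.

    For a mode governed by complex stiffness k_g = k_gR + i k_gI the wave
    damping ratio is proportional to k_gI / k_gR; two modes carry independent
    information exactly when these ratios differ.
    """
    if k_mode.real == 0:
        raise ZeroDivisionError("mode stiffness has zero real part")
    return k_mode.imag / k_mode.real


def p_wave_modulus(mat: ContinuumRDMaterial) -> complex:
    """Complex longitudinal-wave modulus lambda + 2 mu = K + (4/3) mu.

    The real part is K + (4/3) muR.  With a real bulk modulus (the common
    nearly-incompressible soft-tissue assumption) the attenuation is carried
    entirely by the shear loss component, (4/3) muI; a dilatational loss
    component KI, when present, adds linearly.
    """
    re = mat.K + (4.0 / 3.0) * mat.muR
    im = (4.0 / 3.0) * mat.muI + (mat.KI or 0.0)
    return complex(re, im)


def rescale_frequency(mat: RDSpringMaterial, omega_from: float, omega_to: float) -> RDSpringMaterial:
    """Complex pair of a fixed-(alpha, beta) RD material quoted at a new frequency.

    Holding the Rayleigh coefficients constant, the imaginary components scale
    as kI ~ omega (viscoelastic) and mI ~ 1/omega (inertial):
    kI(w2) = kI(w1) * w2/w1 and mI(w2) = mI(w1) * w1/w2.  This is what makes
    multi-frequency data informative: the two damping mechanisms disperse
    differently.
    """
    if omega_from <= 0 or omega_to <= 0:
        raise ValueError("frequencies must be positive")
    s = omega_to / omega_from
    return replace(mat, kI=mat.kI * s, mI=mat.mI / s)
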