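"""Heterogeneous 1D time-harmonic shear-wave solver and RD-vs-VE equivalence.

The scalar restriction of Navier's equation for time-harmonic shear motion
with complex shear modulus mu(x) and complex density rho(x) reads

    d/dx( mu(x) du/dx ) + omega^2 rho(x) u = 0,    u(0), u(L) prescribed.

A generalized-RD material (Im mu >= 0, Im rho <= 0) is *equivalent* to a
viscoelastic material with strictly real density rho_ref iff rescaling the
equation by rho_ref/rho(x) commutes with the spatial derivative — i.e. iff
the complex density profile is homogeneous.  ``ve_equivalence_residual``
measures the failure of that equivalence on a solved field: it is at solver
precision for homogeneous rho (any heterogeneous mu) and order-one for
heterogeneous imaginary density, in which case no VE system reproduces the
motion field and the inertial damping leaves a measurable signature.

Discretization: second-order conservative finite differences in flux form,
with harmonic averaging of mu at the half-nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .springmass_forward import ResonanceError

__all__ = [
    "MaterialProfile1D",
    "Field1D",
    "solve_shear_1d",
    "effective_moduli",
    "ve_equivalence_residual",
    "homogeneous_degeneracy_check",
    "boundary_power_balance",
]


@dataclass(frozen=True)
class MaterialProfile1D:
    """Per-node complex shear modulus and density samples on a uniform grid."""

    mu: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=complex)
        rho = np.asarray(self.rho, dtype=complex)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "rho", rho)
        if mu.shape != rho.shape or mu.ndim != 1:
            raise ValueError("mu and rho must be 1D arrays of equal length")
        if np.any(mu.real <= 0) or np.any(rho.real <= 0):
            raise ValueError("profiles require strictly positive real parts")

    @property
    def homogeneous_rho(self) -> bool:
        return bool(np.allclose(self.rho, self.rho[0], rtol=1e-14, atol=0.0))


@dataclass(frozen=True)
class Field1D:
    """Solved complex displacement field on [0, L]."""

    x: np.ndarray
    u: np.ndarray
    material: MaterialProfile1D
    omega: float

    @property
    def h(self) -> float:
        return float(self.x[1] - self.x[0])


def _half_node_mu(mu: np.ndarray) -> np.ndarray:
    """Harmonic mean of mu on consecutive node pairs (flux continuity)."""
    return 2.0 * mu[:-1] * mu[1:] / (mu[:-1] + mu[1:])


def _flux_residual(mu: np.ndarray, u: np.ndarray, h: float) -> np.ndarray:
    """Interior residual of d/dx(mu du/dx) in conservative form."""
    mh = _half_node_mu(mu)
    flux = mh * np.diff(u) / h
    return np.diff(flux) / h


def solve_shear_1d(
    profile: MaterialProfile1D,
    omega: float,
    left_drive: complex,
    right_drive: complex,
    n_nodes: int | None = None,
    L: float = 1.0,
) -> Field1D:
    """Solve the Dirichlet-driven heterogeneous shear equation.

    ``profile`` must be sampled at the n_nodes uniform nodes (n_nodes
    defaults to the profile length, minimum 32).  Raises
    :class:`ResonanceError` if the discrete operator is singular (a real
    undamped resonance of the medium).
    """
    n = profile.mu.size if n_nodes is None else n_nodes
    if n < 32:
        raise ValueError(f"n_nodes must be >= 32, got {n}")
    if profile.mu.size != n:
        raise ValueError("profile must be sampled at the solver nodes")
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    x = np.linspace(0.0, L, n)
    h = x[1] - x[0]
    mh = _half_node_mu(profile.mu)          # length n-1, half-nodes
    w2 = omega**2

    # interior unknowns u[1..n-2]
    m = n - 2
    lower = mh[1:m] / h**2
    upper = mh[1:m] / h**2
    diag = -(mh[:-1] + mh[1:]) / h**2 + w2 * profile.rho[1:-1]
    ab = np.zeros((3, m), dtype=complex)
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    rhs = np.zeros(m, dtype=complex)
    rhs[0] = -mh[0] / h**2 * left_drive
    rhs[-1] = -mh[-1] / h**2 * right_drive

    try:
        u_int = scipy.linalg.solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - exact singularity
        raise ResonanceError(f"discrete shear operator is singular at omega={omega}") from exc
    drive_scale = max(abs(left_drive), abs(right_drive))
    if not np.all(np.isfinite(u_int)) or np.abs(u_int).max() > 1e10 * drive_scale:
        raise ResonanceError(f"discrete shear operator is (near-)singular at omega={omega}")
    u = np.concatenate([[left_drive], u_int, [right_drive]]).astype(complex)
    return Field1D(x=x, u=u, material=profile, omega=omega)


def effective_moduli(profile: MaterialProfile1D, rho_ref: float) -> np.ndarray:
    """Effective modulus mu_eff(x) = mu(x) * rho_ref / rho(x).

    This is the modulus a strictly-VE model with real density rho_ref must
    have to reproduce the RD equilibrium pointwise; it only yields a
    consistent VE *equation* when rho is homogeneous.
    """
    if rho_ref <= 0:
        raise ValueError("rho_ref must be positive")
    if np.any(np.abs(profile.rho) == 0):
        raise ValueError("rho vanishes at a node")
    return profile.mu * (rho_ref / profile.rho)


def ve_equivalence_residual(field: Field1D, rho_ref: float) -> tuple[float, np.ndarray]:
    """Residual of the candidate equivalent-VE equation on an RD field.

    Evaluates r = d/dx(mu_eff du/dx) + omega^2 rho_ref u at the interior
    nodes of the solved RD field and returns (relative norm, nodal profile),
    the norm being the h-weighted discrete L2 norm normalized by
    ||omega^2 rho_ref u||.  Invariant under rescaling u by any complex
    constant.
    """
    mu_eff = effective_moduli(field.material, rho_ref)
    h = field.h
    r = _flux_residual(mu_eff, field.u, h) + field.omega**2 * rho_ref * field.u[1:-1]
    scale_profile = field.omega**2 * rho_ref * field.u[1:-1]
    num = np.sqrt(h * np.sum(np.abs(r) ** 2))
    den = np.sqrt(h * np.sum(np.abs(scale_profile) ** 2))
    if den == 0:
        raise ValueError("zero field: residual scale undefined")
    return float(num / den), r


def boundary_power_balance(field: Field1D) -> tuple[float, float]:
    """(boundary power input, interior dissipation), time-averaged.

    For u(t) = Re[U e^{i w t}] the mean power input through the two ends is
    P = 1/2 Re[ F conj(i w u) ] with boundary traction F = -+ mu u'; interior
    dissipation is w/2 * int( Im(mu) |u'|^2 - w^2 Im(rho) |u|^2 ) dx, which
    is nonnegative for admissible profiles and equals P in steady state.
    """
    u, h, w = field.u, field.h, field.omega
    rho = field.material.rho
    mh = _half_node_mu(field.material.mu)
    F = mh * np.diff(u) / h          # half-node fluxes
    v = 1j * w * u                   # nodal velocities
    # summation by parts of the (exactly satisfied) interior equations:
    # boundary power equals strain-rate work minus inertial work, discretely
    p_in = 0.5 * np.real(F[-1] * np.conj(v[-1]) - F[0] * np.conj(v[0]))
    strain_work = 0.5 * np.sum(np.real(F * np.conj(np.diff(v))))
    inertial_work = 0.5 * w**2 * h * np.sum(np.real(rho[1:-1] * u[1:-1] * np.conj(v[1:-1])))
    return float(p_in), float(strain_work - inertial_work)


def homogeneous_degeneracy_check(
    profile: MaterialProfile1D,
    omega: float,
    left_drive: complex = 1.0,
    right_drive: complex = 1.0,
    n_nodes: int | None = None,
) -> tuple[bool, np.ndarray | None]:
    """Detect the single-frequency homogeneous-medium solution family.

    Solves the field, then assembles the nodal direct inversion for the
    homogeneous unknowns (muR, muI, rhoI) with rhoR known: each interior node
    contributes the real and imaginary parts of

        (muR + i muI) u''_h + omega^2 (rhoR + i rhoI) u = 0.

    For a homogeneous medium the discrete field satisfies u''_h = lambda u
    with a single complex constant lambda, so the three columns are coplanar:
    the system has rank 2 and a one-dimensional family of (muR, muI, rhoI)
    triples reproduces the data — the classical linear relation between the
    Rayleigh coefficients alpha and beta.  Heterogeneous media break the
    proportionality and the system is full rank.

    Returns (degenerate, unit nullspace direction or None).
    """
    if profile.mu.size < 3:
        raise ValueError("profile too short")
    hom_input = np.allclose(profile.mu, profile.mu[0]) and profile.homogeneous_rho
    field = solve_shear_1d(profile, omega, left_drive, right_drive, n_nodes)
    u, h = field.u, field.h
    upp = (u[2:] - 2.0 * u[1:-1] + u[:-2]) / h**2
    ui = u[1:-1]
    rhoR = float(profile.rho.real.mean())
    w2 = omega**2
    # columns: muR, muI, rhoI ; RHS carries the known rhoR term
    A = np.empty((2 * upp.size, 3))
    b = np.empty(2 * upp.size)
    A[0::2, 0] = upp.real
    A[0::2, 1] = -upp.imag
    A[0::2, 2] = -w2 * ui.imag
    A[1::2, 0] = upp.imag
    A[1::2, 1] = upp.real
    A[1::2, 2] = w2 * ui.real
    b[0::2] = -w2 * rhoR * ui.real
    b[1::2] = -w2 * rhoR * ui.imag
    # nondimensionalize columns (mu-like in rhoR w^2 L^2 units, rho-like in rhoR)
    L = field.x[-1] - field.x[0]
    units = np.array([rhoR * w2 * L**2, rhoR * w2 * L**2, rhoR])
    As = A * units[None, :]
    s = np.linalg.svd(As, compute_uv=False)
    tol = max(As.shape) * s[0] * 1e-8 if s[0] > 0 else np.inf
    rank = int(np.sum(s > tol))
    if not hom_input and rank == 3:
        return False, None
    if not hom_input:
        raise ValueError("heterogeneous profile did not yield a full-rank system")
    _, _, Vt = np.linalg.svd(As)
    direction = Vt[-1] * units
    direction /= np.linalg.norm(direction)
    return rank < 3, direction
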