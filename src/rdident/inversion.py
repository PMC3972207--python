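"""Direct-inversion linear systems for RD parameter identification.

Every measurement of an interior-mass amplitude U at drive frequency omega
satisfies the complex equilibrium

    2 k_mode (U - u0) = omega^2 m U,

where the mode stiffness is, in the most general configuration handled here,

    k_mode = Khat + a kR + i (b s_k kI + KI),      m = mR + i s_m mI,

with a, b relative stiffness/damping factors (a = b = 1 for the shear mode,
a = b = 4/3 on top of a known bulk offset Khat for the longitudinal mode),
and s_k = omega/omega_ref, s_m = omega_ref/omega the Rayleigh-damping
frequency scalings of the imaginary components quoted at omega_ref (both 1
in single-frequency work).  Splitting into real and imaginary parts and
moving known-parameter terms to the right-hand side yields two real linear
equations per complex measurement in the unknowns (kR, kI, mI[, KI]); the
real mass mR is always assumed known (soft tissue density is taken a priori
as that of water).

Rank decisions are made on a nondimensionalized copy of the system (rows
divided by |u0| max(1, omega^2); stiffness-like columns expressed in units
of mR omega_ref^2, mass-like columns in units of mR) so that they do not
depend on unit choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .springmass_forward import ComplexMeasurement

__all__ = [
    "AssemblyError",
    "ConfigurationError",
    "RankDeficientWarning",
    "RANK_RTOL",
    "LinearInverseSystem",
    "IdentifiabilityReport",
    "rows_from_measurement",
    "assemble_case1",
    "assemble_case1_chain",
    "assemble_multifreq",
    "assemble_case3",
    "assemble_case4",
    "assemble_case5",
    "numerical_rank",
    "solve",
]

#: singular value sigma_i counts toward the rank iff
#: sigma_i > max(rows, cols) * sigma_max * RANK_RTOL  (scaled system).
RANK_RTOL = 1e-10

SUPPORTED_UNKNOWNS = ("kR", "kI", "mI", "KI")


class AssemblyError(ValueError):
    """Measurements passed to an assembler are inconsistent with the case."""


class ConfigurationError(ValueError):
    """An unknown-parameter name is not supported."""


class RankDeficientWarning(UserWarning):
    """A configuration known a priori to be rank-deficient was requested."""


@dataclass(frozen=True)
class LinearInverseSystem:
    """Real-valued direct-inversion system A p = b over named unknowns."""

    A: np.ndarray
    b: np.ndarray
    unknowns: tuple[str, ...]
    knowns: dict = field(default_factory=dict)
    omega_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.A.shape != (self.b.size, len(self.unknowns)):
            raise AssemblyError(
                f"shape mismatch: A {self.A.shape}, b {self.b.shape}, "
                f"{len(self.unknowns)} unknowns"
            )

    @property
    def column_units(self) -> np.ndarray:
        """Natural unit of each unknown: mR w_ref^2 for stiffnesses, mR for mass."""
        mR = self.knowns.get("mR", 1.0)
        stiff = mR * self.omega_ref**2
        return np.array([mR if name == "mI" else stiff for name in self.unknowns])

    def scaled(self) -> tuple[np.ndarray, np.ndarray]:
        """(A', b') with dimensionless columns; A' p_dimless = b'."""
        return self.A * self.column_units[None, :], self.b

    def stack(self, other: "LinearInverseSystem") -> "LinearInverseSystem":
        if self.unknowns != other.unknowns:
            raise AssemblyError("cannot stack systems with different unknowns")
        return LinearInverseSystem(
            A=np.vstack([self.A, other.A]),
            b=np.concatenate([self.b, other.b]),
            unknowns=self.unknowns,
            knowns={**self.knowns, **other.knowns},
            omega_ref=self.omega_ref,
        )


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Rank/SVD summary of a direct-inversion system."""

    rank: int
    singular_values: np.ndarray
    condition_number: float
    full_rank: bool
    solution: np.ndarray | None
    nullspace_basis: np.ndarray | None
    unknowns: tuple[str, ...]

    @property
    def nullspace_dim(self) -> int:
        return 0 if self.nullspace_basis is None else self.nullspace_basis.shape[0]

    def as_dict(self) -> dict:
        return {
            "rank": self.rank,
            "singular_values": [float(s) for s in self.singular_values],
            "condition_number": float(self.condition_number),
            "full_rank": self.full_rank,
            "unknowns": list(self.unknowns),
            "solution": None if self.solution is None else
                        {n: float(v) for n, v in zip(self.unknowns, self.solution)},
            "nullspace_basis": None if self.nullspace_basis is None else
                               [[float(v) for v in row] for row in self.nullspace_basis],
        }


def rows_from_measurement(
    meas: ComplexMeasurement,
    mR: float,
    unknowns: tuple[str, ...] = ("kR", "kI", "mI"),
    *,
    a: float = 1.0,
    b: float = 1.0,
    Khat: float = 0.0,
    KI: float = 0.0,
    KI_in_mode: bool = False,
    omega_ref: float | None = None,
    neighbor_mean: complex | None = None,
    scaled: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Two real matrix rows + two RHS entries from one complex measurement.

    The underlying complex equilibrium is ``2 k_mode (U - ubar) = omega^2 m U``
    where ``ubar`` is the mean displacement of the two neighbours
    (``neighbor_mean``; the boundary amplitude u0 for the single-mass case).
    ``KI_in_mode`` marks whether this propagation mode carries the
    dilatational loss KI at all (true only for the axial mode); ``KI`` is its
    known value when "KI" is not among the unknowns.  ``omega_ref`` is the
    frequency at which the imaginary unknowns are quoted; the coefficients of
    kI and mI then carry the Rayleigh frequency scalings omega/omega_ref and
    omega_ref/omega.  Rows are scaled by 1 / (|u0| max(1, omega^2)).
    """
    for name in unknowns:
        if name not in SUPPORTED_UNKNOWNS:
            raise ConfigurationError(f"unsupported unknown {name!r}")
    if not unknowns:
        raise ConfigurationError("unknowns must be nonempty")
    w = meas.omega
    wref = w if omega_ref is None else omega_ref
    s_k = w / wref
    UR, UI = meas.value.real, meas.value.imag
    u0 = meas.u0
    ubar = complex(u0) if neighbor_mean is None else complex(neighbor_mean)
    dR, dI = UR - ubar.real, UI - ubar.imag
    w2 = w * w
    coeff = {
        "kR": (2.0 * a * dR, 2.0 * a * dI),
        "kI": (-2.0 * b * s_k * dI, 2.0 * b * s_k * dR),
        # w^2 * (wref/w) written as w*wref so the static limit w -> 0 is finite
        "mI": (w * wref * UI, -w * wref * UR),
        "KI": (-2.0 * dI, 2.0 * dR) if KI_in_mode else (0.0, 0.0),
    }
    row_re = np.array([coeff[n][0] for n in unknowns])
    row_im = np.array([coeff[n][1] for n in unknowns])
    rhs_re = w2 * mR * UR - 2.0 * Khat * dR
    rhs_im = w2 * mR * UI - 2.0 * Khat * dI
    if KI_in_mode and "KI" not in unknowns and KI != 0.0:
        rhs_re += 2.0 * KI * dI
        rhs_im -= 2.0 * KI * dR
    scale = 1.0 / (abs(u0) * max(1.0, w2)) if scaled else 1.0
    rows = np.vstack([row_re, row_im]) * scale
    rhs = np.array([rhs_re, rhs_im]) * scale
    return rows, rhs


def _system(rows_rhs, unknowns, knowns, omega_ref) -> LinearInverseSystem:
    rows, rhs = zip(*rows_rhs)
    return LinearInverseSystem(
        A=np.vstack(rows), b=np.concatenate(rhs),
        unknowns=unknowns, knowns=knowns, omega_ref=omega_ref,
    )


def assemble_case1(meas: ComplexMeasurement, mR: float) -> LinearInverseSystem:
    """2x3 single-mass, single-frequency system over (kR, kI, mI): rank 2."""
    unknowns = ("kR", "kI", "mI")
    return _system([rows_from_measurement(meas, mR, unknowns)],
                   unknowns, {"mR": mR}, meas.omega)


def assemble_case1_chain(
    meas_list: list[ComplexMeasurement], mR: float
) -> LinearInverseSystem:
    """Stacked system from all interior-mass measurements at one frequency."""
    if not meas_list:
        raise AssemblyError("need at least one measurement")
    omegas = {m.omega for m in meas_list}
    if len(omegas) != 1:
        raise AssemblyError(f"chain measurements span several frequencies: {sorted(omegas)}")
    unknowns = ("kR", "kI", "mI")
    if len(meas_list) == 1:
        rows = [rows_from_measurement(meas_list[0], mR, unknowns)]
    else:
        # interior mass j sits between its chain neighbours; the outermost
        # neighbours are the driven boundaries at u0
        vals = [complex(m.u0) for m in meas_list[:1]] \
             + [m.value for m in meas_list] + [complex(meas_list[-1].u0)]
        rows = [
            rows_from_measurement(
                m, mR, unknowns,
                neighbor_mean=0.5 * (vals[j] + vals[j + 2]),
            )
            for j, m in enumerate(meas_list)
        ]
    return _system(rows, unknowns, {"mR": mR}, meas_list[0].omega)


def assemble_multifreq(
    meas_w1: ComplexMeasurement, meas_w2: ComplexMeasurement, mR: float
) -> LinearInverseSystem:
    """4x3 two-frequency system; unknowns (kR, kI, mI) quoted at omega_1.

    The imaginary components follow the fixed-(alpha, beta) Rayleigh scaling
    across frequency (kI ~ omega, mI ~ 1/omega), which is what renders the
    system generically rank 3.  omega_2 = omega_1 is a known rank-deficient
    configuration and only warns.
    """
    if meas_w1.omega == meas_w2.omega:
        warnings.warn(
            "omega_2 = omega_1 duplicates the single-frequency information: "
            "the system is rank 2", RankDeficientWarning, stacklevel=2,
        )
    unknowns = ("kR", "kI", "mI")
    wref = meas_w1.omega
    rows = [rows_from_measurement(m, mR, unknowns, omega_ref=wref)
            for m in (meas_w1, meas_w2)]
    return _system(rows, unknowns, {"mR": mR}, wref)


def _two_mode_system(
    axial: ComplexMeasurement,
    transverse: ComplexMeasurement,
    mR: float,
    unknowns: tuple[str, ...],
    knowns: dict,
    *,
    a_ax: float,
    b_ax: float,
    Khat: float,
) -> LinearInverseSystem:
    if axial.mode != "axial" or transverse.mode != "transverse":
        raise AssemblyError("expected one axial and one transverse measurement")
    if axial.omega != transverse.omega:
        raise AssemblyError("two-mode assembly requires a single shared frequency")
    rows = [
        rows_from_measurement(axial, mR, unknowns, a=a_ax, b=b_ax, Khat=Khat,
                              KI=knowns.get("KI", 0.0), KI_in_mode=True),
        rows_from_measurement(transverse, mR, unknowns),
    ]
    return _system(rows, unknowns, {"mR": mR, **knowns}, axial.omega)


def assemble_case3(
    axial: ComplexMeasurement, transverse: ComplexMeasurement, Khat: float, mR: float
) -> LinearInverseSystem:
    """4x3 shear + longitudinal system with known real bulk stiffness Khat."""
    return _two_mode_system(axial, transverse, mR, ("kR", "kI", "mI"),
                            {"Khat": Khat}, a_ax=4.0 / 3.0, b_ax=4.0 / 3.0, Khat=Khat)


def assemble_case4(
    axial: ComplexMeasurement, transverse: ComplexMeasurement,
    a: float, b: float, mR: float,
) -> LinearInverseSystem:
    """4x3 two-mode system with relative damping factors; ill posed iff b = a."""
    if b == a:
        warnings.warn(
            "b = a gives equal damping ratios in both modes: the system is rank 2",
            RankDeficientWarning, stacklevel=2,
        )
    return _two_mode_system(axial, transverse, mR, ("kR", "kI", "mI"),
                            {"a": a, "b": b}, a_ax=a, b_ax=b, Khat=0.0)


def assemble_case5(
    axial: ComplexMeasurement, transverse: ComplexMeasurement, Khat: float, mR: float
) -> LinearInverseSystem:
    """4x4 system with dilatational attenuation KI as a fourth unknown."""
    if axial is None or transverse is None:
        raise AssemblyError("case 5 requires both the axial and the transverse mode")
    return _two_mode_system(axial, transverse, mR, ("kR", "kI", "mI", "KI"),
                            {"Khat": Khat}, a_ax=4.0 / 3.0, b_ax=4.0 / 3.0, Khat=Khat)


def numerical_rank(sys: LinearInverseSystem) -> int:
    """SVD rank of the nondimensionalized system with the scaled tolerance rule."""
    A, _ = sys.scaled()
    s = np.linalg.svd(A, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    tol = max(A.shape) * s[0] * RANK_RTOL
    return int(np.sum(s > tol))


def solve(sys: LinearInverseSystem) -> IdentifiabilityReport:
    """Minimum-norm least-squares solution + rank/nullspace report.

    When the system is rank-deficient the returned solution is the
    minimum-norm member of the solution family and ``nullspace_basis`` spans
    the directions along which the data cannot distinguish parameters (the
    Case I two-parameter families).
    """
    A, b = sys.scaled()
    units = sys.column_units
    U, s, Vt = np.linalg.svd(A, full_matrices=True)
    if s.size == 0 or s[0] == 0.0:
        return IdentifiabilityReport(
            rank=0, singular_values=s, condition_number=np.inf, full_rank=False,
            solution=None, nullspace_basis=np.eye(len(sys.unknowns)) / units,
            unknowns=sys.unknowns,
        )
    tol = max(A.shape) * s[0] * RANK_RTOL
    rank = int(np.sum(s > tol))
    full = rank == len(sys.unknowns)
    cond = float(s[0] / s[rank - 1]) if rank > 0 else np.inf
    # minimum-norm LS solution in dimensionless variables, mapped back
    p_dimless = Vt[:rank].T @ ((U[:, :rank].T @ b) / s[:rank])
    solution = p_dimless * units
    nullspace = None
    if rank < len(sys.unknowns):
        ns = Vt[rank:] * units[None, :]
        ns /= np.linalg.norm(ns, axis=1, keepdims=True)
        nullspace = ns
    return IdentifiabilityReport(
        rank=rank, singular_values=s, condition_number=cond, full_rank=full,
        solution=solution, nullspace_basis=nullspace, unknowns=sys.unknowns,
    )
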