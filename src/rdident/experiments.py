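"""Synthetic-measurement generation, recovery studies, dispersion fitting.

Synthetic data come from the closed-form forward models; optional noise is
i.i.d. complex Gaussian applied to the displacement amplitudes only, with
standard deviation ``noise_rel * |U|`` on each of the real and imaginary
parts (a simple stand-in for MRE phase-derived displacement noise).  All
randomness is seeded and outputs are reproducible bit-for-bit per seed.

The multi-frequency dispersion fit extends the two-frequency identification
to materials whose stiffness follows a power law k(omega) =
k_ref (omega/omega_ref)^n while the Rayleigh coefficients (alpha, beta) stay
fixed, so that kI ~ omega^(n+1) and mI ~ 1/omega; with n = 0 the model
reduces exactly to the linear two-frequency system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.optimize

from .rd_model import RDSpringMaterial, rescale_frequency
from .springmass_forward import (
    ComplexMeasurement,
    HarmonicDrive,
    forward_case3,
    forward_case4,
    forward_case5,
    solve_chain,
    transfer_single_mode,
)
from . import inversion

__all__ = [
    "DesignError",
    "DispersionModel",
    "RecoveryResult",
    "DispersionFitResult",
    "generate_measurements",
    "recovery_experiment",
    "multifreq_dispersion_fit",
]


class DesignError(ValueError):
    """The experimental design cannot determine the requested parameters."""


@dataclass(frozen=True)
class DispersionModel:
    """Power-law stiffness dispersion k(omega) = k_ref (omega/omega_ref)^n."""

    k_ref: float
    n: float
    omega_ref: float

    def __post_init__(self) -> None:
        if self.k_ref <= 0 or self.omega_ref <= 0:
            raise ValueError("k_ref and omega_ref must be positive")

    def stiffness(self, omega: float) -> float:
        return self.k_ref * (omega / self.omega_ref) ** self.n


@dataclass(frozen=True)
class RecoveryResult:
    """Per-parameter recovery statistics of a repeated inversion experiment."""

    unknowns: tuple[str, ...]
    truth: np.ndarray
    bias: np.ndarray | None
    rmse: np.ndarray | None
    success: bool
    condition_numbers: np.ndarray
    ranks: np.ndarray
    nullspace_basis: np.ndarray | None
    seed: int
    reps: int


@dataclass(frozen=True)
class DispersionFitResult:
    """Estimates of the power-law RD material from multi-frequency data."""

    k_ref: float
    n: float
    kI_ref: float
    mI_ref: float
    omega_ref: float
    cost: float
    n_starts: int


def _noisy(value: complex, noise_rel: float, rng: np.random.Generator) -> complex:
    if noise_rel == 0.0:
        return value
    g = rng.standard_normal(2)
    return value + noise_rel * abs(value) * complex(g[0], g[1])


def generate_measurements(
    case: str,
    params: RDSpringMaterial,
    frequencies,
    noise_rel: float = 0.0,
    seed: int | None = None,
    u0: float = 1.0,
    **fixed,
) -> list[ComplexMeasurement]:
    """Forward-solve a case and optionally perturb the amplitudes.

    Cases: "I" (single mass, first frequency), "I_chain" (three-mass chain),
    "II" (one single-mass measurement per frequency, fixed alpha/beta across
    frequency), "III"/"IV"/"V" (axial + transverse pair at each frequency;
    ``fixed`` supplies Khat, a/b, KI).  ``noise_rel`` >= 0 is the relative
    complex-Gaussian amplitude; results are deterministic per seed.
    """
    if noise_rel < 0:
        raise ValueError("noise_rel must be nonnegative")
    rng = np.random.default_rng(seed)
    freqs = [float(w) for w in np.atleast_1d(frequencies)]
    case = case.upper()
    out: list[ComplexMeasurement] = []
    if case == "I":
        w = freqs[0]
        U = transfer_single_mode(params.k, params.m, w, u0)
        out = [ComplexMeasurement("transverse", w, u0, U)]
    elif case in ("I_CHAIN", "CHAIN"):
        out = solve_chain([params] * 3, HarmonicDrive(freqs[0], u0))
    elif case == "II":
        if len(freqs) < 2:
            raise DesignError("case II needs at least two frequencies")
        wref = freqs[0]
        for w in freqs:
            mat_w = rescale_frequency(params, wref, w)
            U = transfer_single_mode(mat_w.k, mat_w.m, w, u0)
            out.append(ComplexMeasurement("transverse", w, u0, U))
    elif case in ("III", "IV", "V"):
        for w in freqs:
            da = HarmonicDrive(w, u0, "axial")
            dt = HarmonicDrive(w, u0, "transverse")
            if case == "III":
                ax, tr = forward_case3(params, fixed["Khat"], da, dt)
            elif case == "IV":
                ax, tr = forward_case4(params, fixed["a"], fixed["b"], da, dt)
            else:
                ax, tr = forward_case5(params, fixed["Khat"], fixed["KI"], da, dt)
            out += [ax, tr]
    else:
        raise ValueError(f"unknown case {case!r}")
    return [replace(ms, value=_noisy(ms.value, noise_rel, rng)) for ms in out]


def _assemble(case: str, meas: list[ComplexMeasurement], mR: float, fixed: dict):
    case = case.upper()
    if case == "I":
        return inversion.assemble_case1(meas[0], mR)
    if case in ("I_CHAIN", "CHAIN"):
        return inversion.assemble_case1_chain(meas, mR)
    if case == "II":
        sys = inversion.assemble_multifreq(meas[0], meas[1], mR)
        for extra in meas[2:]:
            sys = sys.stack(inversion.assemble_multifreq(meas[0], extra, mR))
        return sys
    if case == "III":
        return inversion.assemble_case3(meas[0], meas[1], fixed["Khat"], mR)
    if case == "IV":
        return inversion.assemble_case4(meas[0], meas[1], fixed["a"], fixed["b"], mR)
    if case == "V":
        return inversion.assemble_case5(meas[0], meas[1], fixed["Khat"], mR)
    raise ValueError(f"unknown case {case!r}")


def recovery_experiment(
    case: str,
    params: RDSpringMaterial,
    design: dict,
    noise_rel: float = 0.0,
    reps: int = 1,
    seed: int = 0,
) -> RecoveryResult:
    """Repeat generate -> assemble -> solve and report bias/RMSE per unknown.

    ``design`` holds "frequencies" plus the case's fixed inputs (Khat, a, b,
    KI, u0).  A rank-deficient design is reported (success=False with the
    nullspace), not raised.
    """
    design = dict(design)
    freqs = design.pop("frequencies")
    u0 = design.pop("u0", 1.0)
    truth_names = ("kR", "kI", "mI", "KI") if case.upper() == "V" else ("kR", "kI", "mI")
    truth_map = {"kR": params.kR, "kI": params.kI, "mI": params.mI,
                 "KI": design.get("KI", 0.0)}
    truth = np.array([truth_map[n] for n in truth_names])

    child_seeds = np.random.SeedSequence(seed).generate_state(reps)
    estimates = np.full((reps, truth.size), np.nan)
    conds = np.empty(reps)
    ranks = np.empty(reps, dtype=int)
    nullspace = None
    success = True
    import warnings as _warnings
    for r in range(reps):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", inversion.RankDeficientWarning)
            meas = generate_measurements(case, params, freqs, noise_rel,
                                         int(child_seeds[r]), u0, **design)
            report = inversion.solve(_assemble(case, meas, params.mR, design))
        conds[r] = report.condition_number
        ranks[r] = report.rank
        if not report.full_rank:
            success = False
            nullspace = report.nullspace_basis
        elif report.solution is not None:
            estimates[r] = report.solution
    if success:
        bias = estimates.mean(axis=0) - truth
        rmse = np.sqrt(((estimates - truth) ** 2).mean(axis=0))
    else:
        bias = rmse = None
    return RecoveryResult(
        unknowns=truth_names, truth=truth, bias=bias, rmse=rmse, success=success,
        condition_numbers=conds, ranks=ranks, nullspace_basis=nullspace,
        seed=seed, reps=reps,
    )


def dispersion_forward(
    model: DispersionModel,
    kI_ref: float,
    mI_ref: float,
    mR: float,
    frequencies,
    u0: float = 1.0,
) -> list[ComplexMeasurement]:
    """Forward data for a power-law RD material with fixed (alpha, beta).

    At s = omega/omega_ref: kR = k_ref s^n, kI = kI_ref s^(n+1) (constant
    beta riding on the dispersing stiffness), mI = mI_ref / s (constant
    alpha).  n = 0 reproduces the two-frequency linear model exactly.
    """
    out = []
    for w in np.atleast_1d(frequencies):
        s = w / model.omega_ref
        k = complex(model.stiffness(w), kI_ref * s ** (model.n + 1.0))
        m = complex(mR, mI_ref / s)
        out.append(ComplexMeasurement(
            "transverse", float(w), u0, transfer_single_mode(k, m, float(w), u0)))
    return out


def multifreq_dispersion_fit(
    measurements: list[ComplexMeasurement],
    mR: float,
    omega_ref: float | None = None,
    seed: int = 0,
    n_starts: int = 8,
    n_bounds: tuple[float, float] = (-1.0, 2.0),
) -> DispersionFitResult:
    """Nonlinear least-squares fit of (k_ref, n, kI_ref, mI_ref).

    Stacks the real/imaginary equilibrium residuals of every measurement
    under the power-law RD model above and minimizes them over
    (log k_ref, n, kI_ref, mI_ref) with n bounded to ``n_bounds``, using a
    trust-region reflective local solver from ``n_starts`` seeded starts.
    Requires at least 3 distinct frequencies (4 unknowns).
    """
    freqs = sorted({ms.omega for ms in measurements})
    n_params = 4
    if len(freqs) < 3 or 2 * len(freqs) < n_params:
        raise DesignError(
            f"{len(freqs)} distinct frequencies cannot determine {n_params} "
            "dispersion parameters; at least 3 are required"
        )
    wref = freqs[0] if omega_ref is None else float(omega_ref)
    ws = np.array([ms.omega for ms in measurements])
    Us = np.array([ms.value for ms in measurements])
    u0s = np.array([ms.u0 for ms in measurements])
    s_ = ws / wref

    def residuals(p):
        log_kref, n, kI_ref, mI_ref = p
        kR = math.exp(log_kref) * s_**n
        k = kR + 1j * kI_ref * s_ ** (n + 1.0)
        m = mR + 1j * mI_ref / s_
        r = (2.0 * k * (Us - u0s) - ws**2 * m * Us) / (ws**2 * mR * np.abs(Us))
        return np.concatenate([r.real, r.imag])

    # data-driven central start: static-limit stiffness guess from |U|
    k_scale = float(mR * wref**2)
    rng = np.random.default_rng(seed)
    lo = np.array([math.log(k_scale) - 6.0, n_bounds[0], -10.0 * k_scale, -10.0 * mR])
    hi = np.array([math.log(k_scale) + 6.0, n_bounds[1], 10.0 * k_scale, 10.0 * mR])
    best = None
    for i in range(n_starts):
        if i == 0:
            p0 = np.array([math.log(k_scale), 0.0, 0.01 * k_scale, -0.01 * mR])
        else:
            p0 = rng.uniform(
                [math.log(k_scale) - 2.0, n_bounds[0], 0.0, -0.3 * mR],
                [math.log(k_scale) + 2.0, n_bounds[1], 0.3 * k_scale, 0.0],
            )
        sol = scipy.optimize.least_squares(residuals, p0, bounds=(lo, hi),
                                           method="trf", xtol=1e-15, ftol=1e-15,
                                           gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    log_kref, n, kI_ref, mI_ref = best.x
    return DispersionFitResult(
        k_ref=math.exp(log_kref), n=float(n), kI_ref=float(kI_ref),
        mI_ref=float(mI_ref), omega_ref=wref, cost=float(best.cost),
        n_starts=n_starts,
    )
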