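"""Determinant-numerator and rank analysis of the direct-inversion systems.

The 4x3 (Cases II-IV) and 4x4 (Case V) inversion matrices have entries that
are rational functions of the drive frequencies, because the measured
amplitudes are themselves rational in omega.  The determinant of a 3x3
delete-one-row submatrix (or the full 4x4 matrix in Case V) therefore has the
form numerator(s) / denominator(s) in the scan variable s, with the
denominator a product of the strictly positive squared magnitudes
|2 k - omega^2 m|^2.  Configurations that reduce the system rank are exactly
the real roots of the numerators shared by every submatrix.

The numerators are computed exactly (rational arithmetic via sympy) from the
same equilibrium rows the numeric assembly uses; a consistency check against
numeric determinant evaluation guards the transcription.

Scan-variable roots always come in +/- pairs: flipping the sign of a drive
frequency conjugates every measurement and leaves all information content
unchanged.  Root lists are therefore reported as distinct nonnegative
representatives (so "a root at omega2 = omega1" covers +/- omega1); a root at
the origin is the static limit, where the added equations vanish identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import sympy as sp

from .rd_model import RDSpringMaterial, mode_damping_ratio
from .springmass_forward import (
    axial_stiffness_case3,
    axial_stiffness_case4,
    axial_stiffness_case5,
)

__all__ = [
    "IdenticallySingularError",
    "DetNumeratorPoly",
    "det_numerator",
    "real_roots",
    "rank_scan",
    "equal_damping_ratio_condition",
    "RANK_RTOL",
]

#: same scaled-SVD rank rule as inversion.RANK_RTOL
RANK_RTOL = 1e-10

_CASES = ("II", "III", "IV", "V")


class IdenticallySingularError(ValueError):
    """The determinant numerator vanishes identically (rank-deficient everywhere)."""


@dataclass(frozen=True)
class DetNumeratorPoly:
    """Numerator polynomial of a submatrix determinant in the scan variable.

    ``coefficients`` are ascending (constant term first).  ``denominator``
    holds the ascending coefficients of the strictly positive denominator the
    determinant was cleared of, so that
    ``poly(s) == det(submatrix(s)) * denominator(s)`` at every admissible s.
    """

    coefficients: np.ndarray
    scan_variable: str
    case: str
    selector: str
    denominator: np.ndarray

    @property
    def identically_zero(self) -> bool:
        return self.coefficients.size == 0 or not np.any(self.coefficients)

    @property
    def degree(self) -> int:
        return -1 if self.identically_zero else int(np.nonzero(self.coefficients)[0][-1])

    def __call__(self, s):
        return np.polynomial.polynomial.polyval(s, self.coefficients)

    def denominator_at(self, s):
        return np.polynomial.polynomial.polyval(s, self.denominator)


def _sym_rows(U, ubar, w, wref, a, b, Khat, KI, unknowns, KI_in_mode):
    """Symbolic twin of inversion.rows_from_measurement (unscaled rows)."""
    UR, UI = U.as_real_imag()
    dR = sp.together(UR - ubar)
    dI = UI
    s_k = w / wref
    coeff = {
        "kR": (2 * a * dR, 2 * a * dI),
        "kI": (-2 * b * s_k * dI, 2 * b * s_k * dR),
        "mI": (w * wref * UI, -w * wref * UR),
        "KI": ((-2 * dI, 2 * dR) if KI_in_mode else (sp.Integer(0), sp.Integer(0))),
    }
    row_re = [coeff[n][0] for n in unknowns]
    row_im = [coeff[n][1] for n in unknowns]
    return row_re, row_im


def _rat(x) -> sp.Rational:
    return sp.Rational(sp.Float(float(x)))


def _sym_measurement(k, m, w, u0):
    return sp.cancel(2 * k * u0 / (2 * k - w**2 * m))


def _symbolic_system(case: str, mat: RDSpringMaterial, fixed: dict):
    """(rows, scan symbol, scan name) for the requested case.

    Case II stacks the reference-frequency rows with rows at symbolic omega2
    (Rayleigh scaling of the imaginary components); Cases III-V stack the
    axial and transverse rows at a symbolic shared frequency omega.
    """
    kR, kI, mR, mI = map(_rat, (mat.kR, mat.kI, mat.mR, mat.mI))
    u0 = _rat(fixed.get("u0", 1.0))
    unknowns = ("kR", "kI", "mI", "KI") if case == "V" else ("kR", "kI", "mI")
    if case == "II":
        w1 = _rat(fixed["omega1"])
        w2 = sp.Symbol("omega2", real=True)
        rows = []
        for w in (w1, w2):
            k = kR + sp.I * (w / w1) * kI
            m = mR + sp.I * (w1 / w) * mI
            U = _sym_measurement(k, m, w, u0)
            re, im = _sym_rows(U, u0, w, w1, 1, 1, 0, 0, unknowns, False)
            rows += [re, im]
        return rows, w2, "omega2"

    w = sp.Symbol("omega", positive=True)
    k_t = kR + sp.I * kI
    m = mR + sp.I * mI
    if case == "III":
        Khat = _rat(fixed["Khat"])
        a = b = sp.Rational(4, 3)
        k_ax = Khat + a * kR + sp.I * b * kI
        KI_known = sp.Integer(0)
    elif case == "IV":
        a, b = _rat(fixed["a"]), _rat(fixed["b"])
        Khat = sp.Integer(0)
        k_ax = a * kR + sp.I * b * kI
        KI_known = sp.Integer(0)
    elif case == "V":
        Khat = _rat(fixed["Khat"])
        a = b = sp.Rational(4, 3)
        KI_known = _rat(fixed["KI"])
        k_ax = Khat + a * kR + sp.I * (KI_known + b * kI)
    else:
        raise ValueError(f"case must be one of {_CASES}, got {case!r}")
    U_ax = _sym_measurement(k_ax, m, w, u0)
    U_tr = _sym_measurement(k_t, m, w, u0)
    re_a, im_a = _sym_rows(U_ax, u0, w, w, a, b, Khat, KI_known, unknowns, True)
    re_t, im_t = _sym_rows(U_tr, u0, w, w, 1, 1, 0, 0, unknowns, False)
    return [re_a, im_a, re_t, im_t], w, "omega"


def _selector_rows(case: str, selector) -> tuple[list[int], str]:
    """Row indices of the requested submatrix.

    Row order is [re(mode1), im(mode1), re(mode2), im(mode2)] where mode1 is
    the reference frequency (Case II) or the axial mode (Cases III-V).
    "sub1" keeps the real row of the second block, "sub2" its imaginary row;
    "full" (Case V) keeps everything.  An integer deletes that row.
    """
    if selector == "full":
        if case != "V":
            raise ValueError("the full-matrix determinant is square only for case V")
        return [0, 1, 2, 3], "full"
    if case == "V":
        raise ValueError("case V uses the full 4x4 determinant")
    if selector == "sub1":
        return [0, 1, 2], "sub1"
    if selector == "sub2":
        return [0, 1, 3], "sub2"
    if isinstance(selector, int) and 0 <= selector <= 3:
        return [j for j in range(4) if j != selector], f"drop{selector}"
    raise ValueError(f"unsupported submatrix selector {selector!r}")


def det_numerator(
    case: str,
    params: RDSpringMaterial,
    fixed_inputs: dict,
    submatrix_selector="sub1",
) -> DetNumeratorPoly:
    """Exact determinant-numerator polynomial of one submatrix.

    ``fixed_inputs`` carries the case's known quantities: omega1 (II),
    Khat (III), a and b (IV), Khat and KI (V); u0 defaults to 1.
    """
    case = str(case).upper() if not isinstance(case, str) else case.upper()
    if case not in _CASES:
        raise ValueError(f"case must be one of {_CASES}, got {case!r}")
    rows, sym, scan_name = _symbolic_system(case, params, fixed_inputs)
    keep, sel_name = _selector_rows(case, submatrix_selector)
    M = sp.Matrix([rows[j] for j in keep])
    det = sp.cancel(sp.together(M.det()))
    num, den = sp.fraction(det)
    num = sp.expand(num)
    if num == 0:
        coeffs = np.array([])
        den_coeffs = np.array([float(c) for c in sp.Poly(den, sym).all_coeffs()][::-1]) \
            if den.has(sym) else np.array([float(den)])
        return DetNumeratorPoly(coeffs, scan_name, case, sel_name, den_coeffs)
    pnum = sp.Poly(num, sym)
    pden = sp.Poly(den, sym)
    # normalize so the denominator is positive at a probe point inside the
    # admissible range (it is a product of squared magnitudes up to sign)
    probe = sp.Rational(7, 5)
    dval = pden.eval(probe)
    if dval < 0:
        pnum, pden = -pnum, -pden
    # exact integer coefficients can be astronomically large once the binary
    # rationals are cleared; rescale the (numerator, denominator) pair jointly
    # so poly = det * denominator is preserved and floats stay in range
    cmax = max(abs(c) for c in pnum.all_coeffs())
    coeffs = np.array([float(c / cmax) for c in pnum.all_coeffs()[::-1]])
    den_coeffs = np.array([float(c / cmax) for c in pden.all_coeffs()[::-1]])
    return DetNumeratorPoly(coeffs, scan_name, case, sel_name, den_coeffs)


def real_roots(
    poly: DetNumeratorPoly,
    *,
    fold_sign: bool = True,
    imag_tol: float = 1e-8,
    dedupe_rtol: float = 1e-6,
) -> list[float]:
    """Distinct real roots of a determinant numerator, sorted ascending.

    Roots are the eigenvalues of the companion matrix, kept when
    ``|Im r| < imag_tol * (1 + |Re r|)`` and deduplicated at relative
    ``dedupe_rtol``.  With ``fold_sign`` (default) the +/- pairs are folded
    onto their nonnegative representatives, since the sign of a drive
    frequency carries no information.
    """
    if poly.identically_zero:
        raise IdenticallySingularError(
            "determinant numerator is identically zero: the system is "
            "rank-deficient at every scan value"
        )
    roots = np.polynomial.polynomial.polyroots(poly.coefficients)
    reals = sorted(r.real for r in roots if abs(r.imag) < imag_tol * (1 + abs(r.real)))
    if fold_sign:
        reals = sorted(abs(r) for r in reals)
    out: list[float] = []
    for r in reals:
        if not out or abs(r - out[-1]) > dedupe_rtol * (1 + abs(out[-1])):
            out.append(float(r))
    return out


# ---------------------------------------------------------------------------
# vectorized rank scans
# ---------------------------------------------------------------------------


def _batch_rows(U, ubar, w, wref, a, b, n_cols, KI_col):
    """(N, 2, n_cols) real row blocks for vectorized measurements U(w).

    ``wref=None`` quotes the imaginary unknowns at each point's own frequency.
    """
    N = np.broadcast(U, w).size
    U = np.broadcast_to(U, (N,)).astype(complex)
    w = np.broadcast_to(np.asarray(w, dtype=float), (N,))
    if wref is None:
        wref = w
    dR, dI = U.real - ubar, U.imag
    s_k = w / wref
    rows = np.zeros((N, 2, n_cols))
    rows[:, 0, 0] = 2 * a * dR
    rows[:, 1, 0] = 2 * a * dI
    rows[:, 0, 1] = -2 * b * s_k * dI
    rows[:, 1, 1] = 2 * b * s_k * dR
    rows[:, 0, 2] = w * wref * U.imag
    rows[:, 1, 2] = -w * wref * U.real
    if KI_col:
        rows[:, 0, 3] = -2 * dI
        rows[:, 1, 3] = 2 * dR
    scale = 1.0 / np.maximum(1.0, w**2)
    return rows * scale[:, None, None]


def _meas(k, m, w, u0=1.0):
    return 2 * k * u0 / (2 * k - w**2 * m)


def rank_scan(
    case: str,
    params: RDSpringMaterial,
    scan_grid: Sequence[float],
    with_sigma_min: bool = False,
    **fixed,
) -> list[tuple]:
    """Numerical rank of the assembled inversion system along a scan.

    Scan variable per case: II -> omega2 (omega1 in ``fixed``); III -> the
    shared drive frequency omega; IV -> the damping factor b at fixed ``a``
    and ``omega``; V -> the longitudinal loss ratio (the dilatational loss KI
    is set so that Im(k_long)/Re(k_long) equals the scan value, with the
    equal-ratio point b = a included), at fixed ``Khat`` and ``omega``.
    Rank drops occur exactly at the real roots of the corresponding
    determinant numerators.
    """
    case = case.upper()
    grid = np.asarray(scan_grid, dtype=float)
    kR, kI, mR, mI = params.kR, params.kI, params.mR, params.mI
    u0 = float(fixed.get("u0", 1.0))
    k = complex(kR, kI)
    m = complex(mR, mI)

    if case == "II":
        w1 = float(fixed["omega1"])
        U1 = _meas(k, m, w1, u0)
        block1 = _batch_rows(np.array([U1]), u0, np.array([w1]), w1, 1, 1, 3, False)[0]
        w2 = grid
        k2 = kR + 1j * kI * w2 / w1
        m2 = mR + 1j * mI * w1 / np.where(w2 == 0.0, np.inf, w2)
        U2 = np.where(w2 == 0.0, u0 + 0j, _meas(k2, m2, np.where(w2 == 0, 1, w2), u0))
        block2 = _batch_rows(U2, u0, w2, w1, 1, 1, 3, False)
        A = np.concatenate([np.broadcast_to(block1, (grid.size, 2, 3)), block2], axis=1)
        units = np.array([mR * w1**2, mR * w1**2, mR])
    elif case in ("III", "IV", "V"):
        if case == "III":
            k_ax = axial_stiffness_case3(params, float(fixed["Khat"]))
            a = b = 4.0 / 3.0
            k_ax_grid = np.full(grid.size, k_ax)
            w = grid.astype(float)
        elif case == "IV":
            a = float(fixed["a"])
            w = np.full(grid.size, float(fixed["omega"]))
            k_ax_grid = a * kR + 1j * grid * kI
            b = None  # per-point, handled below
        else:
            Khat = float(fixed["Khat"])
            a = b = 4.0 / 3.0
            w = np.full(grid.size, float(fixed["omega"]))
            kpR = Khat + 4.0 * kR / 3.0
            KI_grid = grid * kpR - 4.0 * kI / 3.0  # loss-ratio parameterization
            k_ax_grid = kpR + 1j * (KI_grid + 4.0 * kI / 3.0)
        n_cols = 4 if case == "V" else 3
        U_ax = _meas(k_ax_grid, m, w, u0)
        U_tr = _meas(k, m, w, u0)
        if case == "IV":
            ax = np.stack([
                _batch_rows(np.array([U_ax[i]]), u0, np.array([w[i]]), w[i],
                            a, grid[i], n_cols, False)[0]
                for i in range(grid.size)
            ])
        else:
            ax = _batch_rows(U_ax, u0, w, None, a, b, n_cols, case == "V")
            # per-point omega_ref = omega itself
        tr = _batch_rows(U_tr, u0, w, None, 1.0, 1.0, n_cols, False)
        A = np.concatenate([ax, tr], axis=1)
        units_grid = np.stack([
            np.full(grid.size, mR) if name == "mI" else mR * w**2
            for name in (("kR", "kI", "mI", "KI") if case == "V" else ("kR", "kI", "mI"))
        ], axis=1)
        s = np.linalg.svd(A * units_grid[:, None, :], compute_uv=False)
    else:
        raise ValueError(f"case must be one of {_CASES}, got {case!r}")

    if case == "II":
        s = np.linalg.svd(A * units[None, None, :], compute_uv=False)
    tol = max(A.shape[1], A.shape[2]) * s[:, :1] * RANK_RTOL
    ranks = (s > tol).sum(axis=1)
    if with_sigma_min:
        return [(float(g), int(r), float(sv[-1]))
                for g, r, sv in zip(grid, ranks, s)]
    return [(float(g), int(r)) for g, r in zip(grid, ranks)]


def equal_damping_ratio_condition(
    k_shear: complex, k_long: complex, rtol: float = 1e-12
) -> bool:
    """True iff the VE loss ratios of the two propagation modes are equal.

    The loss ratio Im(k)/Re(k) of a mode sets its wave damping ratio; when
    the shear and longitudinal ratios coincide (b = a in the relative-factor
    parameterization) the second mode adds no information and the two-mode
    inversion drops to rank 2.
    """
    r_s = mode_damping_ratio(complex(k_shear))
    r_l = mode_damping_ratio(complex(k_long))
    scale = max(abs(r_s), abs(r_l), 1e-300)
    return abs(r_s - r_l) <= rtol * max(1.0, scale)
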