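from fractions import Fraction

import numpy as np
import pytest
import sympy as sp

from rdident import experiments
from rdident.inversion import (
    AssemblyError,
    ConfigurationError,
    RankDeficientWarning,
    assemble_case1,
    assemble_case1_chain,
    assemble_case3,
    assemble_case4,
    assemble_case5,
    assemble_multifreq,
    numerical_rank,
    rows_from_measurement,
    solve,
)
from rdident.rd_model import RDSpringMaterial
from rdident.springmass_forward import ComplexMeasurement
from conftest import draw_material, draw_omega


def gen(case, mat, freqs, **fixed):
    return experiments.generate_measurements(case, mat, freqs, **fixed)


def assemble(case, mat, freqs, **fixed):
    meas = gen(case, mat, freqs, **fixed)
    return experiments._assemble(case, meas, mat.mR, fixed)


def truth(mat, fixed=(), case="I"):
    p = [mat.kR, mat.kI, mat.mI]
    if case == "V":
        p.append(dict(fixed)["KI"])
    return np.array(p)


class TestRowsFromMeasurement:
    def test_static_measurement_gives_degenerate_stiffness_rows(self, material):
        meas = ComplexMeasurement("transverse", 1e-9, 1.0, 1.0 + 0j)
        rows, rhs = rows_from_measurement(meas, material.mR)
        assert np.allclose(rows[:, :2], 0.0)  # kR, kI columns vanish

    def test_conjugated_measurement_flips_imaginary_row(self, material):
        w = 0.8
        U = experiments.generate_measurements("I", material, [w])[0].value
        m = ComplexMeasurement("transverse", w, 1.0, U)
        mc = ComplexMeasurement("transverse", w, 1.0, U.conjugate())
        r, _ = rows_from_measurement(m, material.mR)
        rc, _ = rows_from_measurement(mc, material.mR)
        # time-convention flip: real row of the kR column unchanged, imaginary negated
        assert rc[0, 0] == pytest.approx(r[0, 0])
        assert rc[1, 0] == pytest.approx(-r[1, 0])

    def test_unknown_name_rejected(self, material):
        meas = ComplexMeasurement("transverse", 1.0, 1.0, 0.5 + 0.1j)
        with pytest.raises(ConfigurationError):
            rows_from_measurement(meas, material.mR, unknowns=("kR", "bogus"))


class TestForwardInverseConsistency:
    """Noiseless assembly must satisfy A p_true = b for every case."""

    def test_consistency_200_draws(self, rng):
        for _ in range(200):
            mat = draw_material(rng)
            w = draw_omega(rng, mat)
            w2 = draw_omega(rng, mat)
            configs = [
                ("I", [w], {}),
                ("I_CHAIN", [w], {}),
                ("II", sorted({w, w2}) if w != w2 else [w, 1.1 * w], {}),
                ("III", [w], {"Khat": 1e4 * mat.kR}),
                ("IV", [w], {"a": rng.uniform(1.0, 3.0), "b": rng.uniform(0.1, 3.0)}),
                ("V", [w], {"Khat": 1e4 * mat.kR,
                            "KI": rng.uniform(0.0, 0.3) * 1e4 * mat.kR}),
            ]
            for case, freqs, fixed in configs:
                sys = assemble(case, mat, freqs, **fixed)
                p = truth(mat, fixed.items(), case)
                resid = np.linalg.norm(sys.A @ p - sys.b)
                scale = np.linalg.norm(sys.A) * np.linalg.norm(p) + np.linalg.norm(sys.b)
                assert resid <= 1e-10 * scale, (case, resid, scale)

    def test_full_rank_recovery_to_1e8(self, rng):
        for _ in range(50):
            mat = draw_material(rng)
            w = draw_omega(rng, mat)
            configs = [
                ("II", [w, 1.37 * w], {}),
                ("III", [w], {"Khat": 1e4 * mat.kR}),
                ("IV", [w], {"a": 2.0, "b": 0.5}),
            ]
            for case, freqs, fixed in configs:
                rep = solve(assemble(case, mat, freqs, **fixed))
                assert rep.full_rank, case
                p = truth(mat, fixed.items(), case)
                assert np.allclose(rep.solution, p, rtol=1e-8), case


class TestRanks:
    def test_case1_single_measurement_rank2(self, material):
        assert numerical_rank(assemble("I", material, [0.7])) == 2

    def test_case1_chain_still_rank2(self, material):
        sys = assemble("I_CHAIN", material, [0.7])
        assert sys.A.shape == (6, 3)
        assert numerical_rank(sys) == 2

    def test_all_zero_measurement_degenerate(self, material):
        meas = ComplexMeasurement("transverse", 0.7, 1.0, 0j)
        sys = assemble_case1(meas, material.mR)
        # the measurement-dependent mI column collapses; only the u0 offsets
        # in the stiffness columns survive, and mI spans the nullspace
        assert np.allclose(sys.A[:, 2], 0.0)
        rep = solve(sys)
        assert rep.rank == 2
        assert rep.nullspace_dim == 1
        assert abs(rep.nullspace_basis[0][2]) == pytest.approx(1.0)

    def test_multifreq_generic_rank3(self, material):
        assert numerical_rank(assemble("II", material, [0.7, 1.1])) == 3

    def test_multifreq_repeated_frequency_rank2_and_warns(self, material):
        meas = gen("I", material, [0.7]) * 2
        with pytest.warns(RankDeficientWarning):
            sys = assemble_multifreq(meas[0], meas[1], material.mR)
        assert numerical_rank(sys) == 2

    def test_multifreq_undamped_returns_zero_damping(self):
        mat = RDSpringMaterial(kR=1.0, mR=1.0)
        rep = solve(assemble("II", mat, [0.7, 1.1]))
        assert rep.full_rank
        assert rep.solution[1] == pytest.approx(0.0, abs=1e-12)
        assert rep.solution[2] == pytest.approx(0.0, abs=1e-12)

    def test_case3_rank3_and_exact_recovery(self, material):
        rep = solve(assemble("III", material, [0.7], Khat=1e4))
        assert rep.rank == 3
        assert np.allclose(rep.solution, [material.kR, material.kI, material.mI],
                           rtol=1e-8)

    def test_case4_equal_damping_ratios_rank2(self, material):
        with pytest.warns(RankDeficientWarning):
            sys = assemble("IV", material, [0.7], a=1.5, b=1.5)
        assert numerical_rank(sys) == 2

    def test_case5_full_rank_even_with_matched_ratios(self, material):
        Khat = 1e4
        # dilatational loss chosen so both modes share one loss ratio
        KI = material.kI / material.kR * (Khat + 4 * material.kR / 3) - 4 * material.kI / 3
        sys = assemble("V", material, [0.7], Khat=Khat, KI=KI)
        assert sys.A.shape == (4, 4)
        assert numerical_rank(sys) == 4

    def test_rank_never_increases_when_rows_removed(self, rng):
        from rdident.inversion import LinearInverseSystem

        for _ in range(20):
            mat = draw_material(rng)
            w = draw_omega(rng, mat)
            sys = assemble("II", mat, [w, 1.29 * w])
            r_full = numerical_rank(sys)
            for drop in range(sys.A.shape[0]):
                keep = [j for j in range(sys.A.shape[0]) if j != drop]
                sub = LinearInverseSystem(sys.A[keep], sys.b[keep], sys.unknowns,
                                          sys.knowns, sys.omega_ref)
                assert numerical_rank(sub) <= r_full

    def test_duplicated_measurements_do_not_increase_rank(self, material):
        meas = gen("I", material, [0.7])
        sys1 = assemble_case1(meas[0], material.mR)
        sys2 = sys1.stack(sys1)
        assert numerical_rank(sys2) == numerical_rank(sys1)


class TestSolveReports:
    def test_case1_nullspace_family_satisfies_system(self, material):
        sys = assemble("I", material, [0.7])
        rep = solve(sys)
        assert not rep.full_rank
        assert rep.nullspace_dim == 1
        for t in (-2.0, 0.0, 3.7):
            p = rep.solution + t * rep.nullspace_basis[0]
            assert np.allclose(sys.A @ p, sys.b, atol=1e-12)

    def test_zero_matrix_rank0(self):
        from rdident.inversion import LinearInverseSystem

        sys = LinearInverseSystem(np.zeros((2, 3)), np.zeros(2),
                                  ("kR", "kI", "mI"), {"mR": 1.0}, 1.0)
        rep = solve(sys)
        assert rep.rank == 0 and rep.solution is None

    def test_report_serializes(self, material):
        d = solve(assemble("III", material, [0.7], Khat=1e4)).as_dict()
        assert d["full_rank"] and set(d["solution"]) == {"kR", "kI", "mI"}


class TestAssemblyErrors:
    def test_chain_frequencies_must_match(self, material):
        m1 = gen("I", material, [0.7])[0]
        m2 = gen("I", material, [0.9])[0]
        with pytest.raises(AssemblyError):
            assemble_case1_chain([m1, m2], material.mR)

    def test_case5_requires_both_modes(self, material):
        ax, tr = gen("V", material, [0.7], Khat=1e4, KI=0.1)
        with pytest.raises(AssemblyError):
            assemble_case5(tr, tr, 1e4, material.mR)

    def test_two_mode_frequencies_must_match(self, material):
        ax, _ = gen("III", material, [0.7], Khat=1e4)
        _, tr = gen("III", material, [0.9], Khat=1e4)
        with pytest.raises(AssemblyError):
            assemble_case3(ax, tr, 1e4, material.mR)


class TestExactRationalRankOracle:
    """Numerical rank must agree with exact rational-arithmetic rank."""

    @staticmethod
    def _exact_case1_rows(kR, kI, mR, mI, w, u0=1):
        k = kR + sp.I * kI
        m = mR + sp.I * mI
        U = sp.cancel(2 * k * u0 / (2 * k - w**2 * m))
        UR, UI = U.as_real_imag()
        return [
            [2 * (UR - u0), -2 * UI, w**2 * UI],
            [2 * UI, 2 * (UR - u0), -w**2 * UR],
        ], U

    def test_rank_matches_exact_fractions(self, rng):
        for i in range(25):
            kR = Fraction(int(rng.integers(1, 8)), int(rng.integers(1, 4)))
            kI = kR * Fraction(int(rng.integers(1, 6)), 20)
            mR = Fraction(int(rng.integers(1, 8)), int(rng.integers(1, 4)))
            mI = -mR * Fraction(int(rng.integers(1, 6)), 20)
            w = Fraction(int(rng.integers(2, 12)), 10)
            rows, U = self._exact_case1_rows(*map(sp.Rational, (kR, kI, mR, mI, w)))
            exact_rank = sp.Matrix(rows).rank()
            meas = ComplexMeasurement("transverse", float(w), 1.0, complex(U))
            sys = assemble_case1(meas, float(mR))
            assert numerical_rank(sys) == exact_rank == 2

    def test_two_frequency_rank_matches_exact_fractions(self, rng):
        for i in range(25):
            kR, mR = sp.Rational(3, 2), sp.Rational(1, 1)
            kI = kR * sp.Rational(int(rng.integers(1, 7)), 20)
            mI = -mR * sp.Rational(int(rng.integers(1, 7)), 20)
            w1 = sp.Rational(int(rng.integers(4, 9)), 10)
            w2 = w1 if i % 5 == 0 else sp.Rational(int(rng.integers(10, 16)), 10)
            rows = []
            meas = []
            for w in (w1, w2):
                k = kR + sp.I * (w / w1) * kI
                m = mR + sp.I * (w1 / w) * mI
                U = sp.cancel(2 * k / (2 * k - w**2 * m))
                UR, UI = U.as_real_imag()
                s = w / w1
                rows += [
                    [2 * (UR - 1), -2 * s * UI, w * w1 * UI],
                    [2 * UI, 2 * s * (UR - 1), -w * w1 * UR],
                ]
                meas.append(ComplexMeasurement("transverse", float(w), 1.0, complex(U)))
            exact_rank = sp.Matrix(rows).rank()
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RankDeficientWarning)
                sys = assemble_multifreq(meas[0], meas[1], float(mR))
            assert numerical_rank(sys) == exact_rank
            assert exact_rank == (2 if w2 == w1 else 3)
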