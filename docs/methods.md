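# Methods

## Model

Time-harmonic displacements u(x, t) = Re[U(x) e^{+iωt}] in a generalized
Rayleigh-damped (RD) medium are governed by complex material parameters: a
complex shear modulus μ = μ_R + iμ_I and a complex density ρ = ρ_R + iρ_I.
The two imaginary components encode physically distinct attenuation
mechanisms — μ_I resists strain rate (viscoelastic damping), ρ_I resists
local velocity (inertial damping, the analogue of a matrix moving through a
stationary viscous fluid). Under the e^{+iωt} convention used throughout,
dissipativity requires μ_I ≥ 0 (spring analogue k_I ≥ 0) and ρ_I ≤ 0
(m_I ≤ 0); the map to classical Rayleigh coefficients C = αM + βK is

    k = k_R (1 + iωβ)  →  β = k_I / (ω k_R),
    m = m_R (1 − iα/ω) →  α = −ω m_I / m_R,

and the damping ratio is ξ(ω) = (α/ω + βω)/2, minimized at ω = √(α/β).
Validation is strict by default; `allow_gain=True` opts out so degenerate
sign configurations can still be studied. A material constructed for the
opposite time convention is obtained by conjugation (`complex_pair("-iwt")`).

## Spring-mass analogy

The elastography setting — interior motion measured, boundary forces
unknown — is modelled by interior masses between springs whose ends are
displacement-driven at amplitude u0. The single-mass unit has the exact
transfer

    U = 2 k u0 / (2 k − ω² m),

singular only at the undamped resonance ω² = 2k_R/m_R (guarded by a
scale-invariant tolerance |2k − ω²m| < 1e−10·|2k|). The three-mass,
four-spring chain is solved as an exact 3×3 complex tridiagonal system. Two
propagation modes are treated as independent scalar systems sharing the
complex mass: the transverse (shear) mode uses k, the axial (longitudinal)
mode uses, depending on the study,

- a near-rigid known bulk offset: k_p = (K̂ + 4k_R/3) + i(4k_I/3), K̂ ≫ k_R
  (the nearly incompressible soft-tissue case with a real bulk modulus; the
  continuum p-wave modulus is λ + 2μ = K + 4μ/3);
- free relative factors: k_p = a·k_R + i·b·k_I;
- dilatational attenuation: k_p = (K̂ + 4k_R/3) + i(K_I + 4k_I/3).

## Direct inversion and rank analysis

Each complex measurement yields one complex equilibrium equation
2 k_mode (U − ū) = ω² m U (ū is the mean of the two neighbour
displacements; u0 for the single-mass unit). Splitting into real and
imaginary parts and moving known terms (m_R, K̂, known K_I) to the
right-hand side gives two real equations, linear in the unknowns
(k_R, k_I, m_I[, K_I]). m_R is always known — the density-of-water
assumption standard in soft-tissue elastography.

**Multi-frequency data needs the Rayleigh frequency scaling.** If the complex
pair (k, m) were held frequency-independent, measurements at any number of
frequencies would determine only the complex ratio m/k: every added frequency
repeats the same two equations and the system stays rank 2 (this is provable
in two lines from the transfer function, and the package's exact-rational
rank oracle confirms it). What makes a second frequency informative is that
the two damping mechanisms disperse differently when (α, β) are fixed
material constants: k_I(ω) = ωβk_R grows with ω while m_I(ω) = −αm_R/ω
decays. The two-frequency system therefore quotes the unknowns at ω₁ and
scales the k_I and m_I columns by ω/ω₁ and ω₁/ω respectively. With that
structure the 4×3 system is generically rank 3.

**Determinant numerators.** The matrix entries are rational functions of the
drive frequency, with strictly positive denominators |2k − ω²m|². Rank
deficiency occurs exactly where all 3×3 minors vanish, i.e. at common real
roots of the determinant *numerators*. These polynomials are computed
exactly: material floats are promoted to rationals, the symbolic measurement
is formed from the same row construction the numeric assembler uses, and the
submatrix determinant is cleared of its denominator with sympy. A
consistency invariant (polynomial = numeric determinant × denominator at
random scan points, relative 1e−8) guards the transcription, and an
interpolation-style numeric evaluation serves as the test oracle. Two
conventions: "sub1"/"sub2" keep the first mode's (or frequency's) two rows
plus the real/imaginary row of the second; roots are reported as distinct
nonnegative representatives because scan-variable sign flips only conjugate
the data. A root at the origin is the static limit, where the added
equations vanish identically (no information), outside the admissible drive
domain ω > 0.

The resulting structure, verified per draw by `rank_scan`:

- one frequency, one mode: rank 2; adding chain masses leaves rank 2;
- two frequencies: rank 3 except at ω₂ ∈ {0, ω₁} (the common submatrix
  roots); the undamped-resonance root √(2k_R/m_R) appears only in sub2 and
  does not reduce the rank;
- two modes, one frequency: rank 3 at every real frequency when the mode
  loss ratios differ (sub1 has no positive real roots; sub2's only root is
  the shear undamped resonance, again harmless);
- relative factors: both numerators share the factor (b − a), so the system
  is rank 2 exactly at b = a — equal damping ratios in the two modes, no
  independent second observation;
- dilatational attenuation as a fourth unknown: the full 4×4 determinant has
  no positive real roots for plausible draws (K̂/k_R ∈ [10³, 10⁶], loss
  ratios ≤ 0.5, matched-ratio configurations included), removing the b = a
  singularity.

**Numerical rank rule.** σᵢ counts iff σᵢ > max(rows, cols)·σ_max·1e−10,
applied to a nondimensionalized system: rows are divided by |u0|·max(1, ω²)
and columns are expressed in natural units (stiffness-like unknowns in
m_R ω_ref², mass-like in m_R), so rank decisions are invariant to unit
choices. `solve` returns the SVD minimum-norm solution plus a nullspace
basis, so rank-deficient cases expose their solution family (e.g. the
one-dimensional (k_R, k_I, m_I) family of the single-frequency case — the
classical linear α–β relation).

## 1D continuum and RD↔VE equivalence

The scalar shear restriction of Navier's equation,
d/dx(μ(x) u′) + ω²ρ(x) u = 0 with Dirichlet (displacement-driven) ends, is
discretized by second-order conservative finite differences in flux form
with harmonic averaging of μ at half-nodes, and solved with a banded complex
solver (default 512 nodes). Verified second-order convergence against the
homogeneous standing-wave solution and a manufactured traveling wave in an
exponentially graded medium; the discrete energy identity (boundary power =
μ_I- and ρ_I-weighted interior dissipation) holds to machine precision by
summation by parts.

A strictly-VE medium with real reference density ρ_ref reproduces an RD
field only if rescaling the equation by ρ_ref/ρ(x) commutes with d/dx, i.e.
iff the complex density profile is homogeneous. `ve_equivalence_residual`
measures the defect of the candidate equivalent equation
d/dx(μ_eff u′) + ω²ρ_ref u with μ_eff = μ·ρ_ref/ρ, as an h-weighted L2 norm
normalized by ‖ω²ρ_ref u‖ (invariant under rescaling u). For homogeneous ρ
the residual is at solver precision *exactly* (the discrete operator is
linear in μ); for heterogeneous ρ the defect term is μu′·d(ρ_ref/ρ)/dx, so
the residual is **first order** in the density contrast and order-one for a
step in ρ_I — the inertial damping signature that precludes any VE
equivalent. The one-dimensional homogeneous solution family is detected by
`homogeneous_degeneracy_check`, which assembles the nodal inversion over
(μ_R, μ_I, ρ_I) with ρ_R known: a homogeneous field satisfies u″ = λu with
one complex constant, the three columns are coplanar, and the system has
rank 2 (heterogeneous media break the proportionality and are full rank).
The real stiffness must be among the unknowns for this degeneracy to exist;
with μ_R also known the two equations determine the two imaginary parts.

## Synthetic data and experiments

Noise, when requested, is i.i.d. complex Gaussian on the displacement
amplitudes with per-component standard deviation noise_rel·|U| — a simple
emulation of MRE phase-derived displacement noise. It deliberately omits
spatial correlation, phase wrapping, and amplitude-dependent SNR of real
acquisitions, so passing recovery tests demonstrate correctness of the
inversion algebra and conditioning trends, not robustness on scanner data
(direct inversion is known to be noise-sensitive; regularization is out of
scope). All randomness is seeded (numpy Generator); results are reproducible
bit-for-bit per (configuration, seed).

The dispersion study models a power-law stiffness k_R(ω) = k_ref(ω/ω_ref)^n
with *fixed* Rayleigh coefficients riding on it: k_I ∝ ω^{n+1}, m_I ∝ 1/ω.
With n = 0 this reduces exactly to the linear two-frequency model, which the
fit reproduces. The fit minimizes stacked normalized equilibrium residuals
over (log k_ref, n, k_I_ref, m_I_ref), n bounded to [−1, 2], with a
trust-region-reflective local solver from 8 seeded starts (one data-driven
central start plus 7 random); at least 3 distinct frequencies are required
for the 4 parameters. The log-parameterization keeps k_ref positive; whether
the power law should also apply to the damping components is exposed through
the generator rather than hard-coded — the default ties them to constant
(α, β), the package's RD reading.

## Default study conditions and problem sizes

Generic parameter draws use k_R, m_R ∈ [0.5, 2] (nondimensional units),
loss ratios ∈ [0.02, 0.3], drive frequencies in [0.3, 0.9]× the undamped
resonance, u0 = 1; the near-incompressible bulk offset is K̂ = 10⁴·k_R
(ratio configurable, flag threshold K/μ_R ≥ 10⁴); plausibility draws for the
dilatational study widen loss ratios to (0.005, 0.5] and K̂/k_R to
[10³, 10⁶]. Frequency rank scans use 2000-point grids over
[0.01, 10]×resonance; the continuum tests use 512 nodes on [0, 1] with a
contrast-2 step in ρ_I at mid-domain. These sizes resolve every structural
feature (root locations, interface defects) with large margin while the full
suite runs in seconds.

## Known limitations

- Identifiability conclusions are verified numerically at sampled parameters,
  not proven symbolically for arbitrary parameter values.
- The continuum solver is 1D scalar shear only; dilatational physics is
  covered by the spring analogy, not by a 2D/3D continuum model.
- No regularization or spatially resolved reconstruction: the package
  characterizes posedness of the local direct inversion, not image quality.
- Exact-rational determinant numerators inherit the binary expansions of
  float inputs; coefficients are jointly rescaled to keep evaluation in
  floating-point range, and root finding is then performed in floats.
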