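# rdident

Identifiability analysis for **generalized time-harmonic Rayleigh damping
(RD)** in elastography.

Elastography reconstructs tissue mechanical properties from measured internal
displacement fields under time-harmonic excitation. Attenuation carries
diagnostic information, but the common viscoelastic (VE) model ties all
attenuation to a single parameter, the shear loss modulus μ_I. The
generalized RD model instead works with a complex shear modulus **and** a
complex density,

    mu = mu_R + i mu_I,        rho = rho_R + i rho_I,

whose imaginary parts vary independently: μ_I models strain-rate
(viscoelastic) damping and ρ_I models damping proportional to local velocity,
as if the solid matrix moved through a stationary viscous fluid. Under the
package's e^{+iωt} time convention, dissipative materials have μ_I ≥ 0 and
ρ_I ≤ 0, corresponding to classical Rayleigh coefficients (C = αM + βK)

    beta = mu_I / (omega mu_R),        alpha = -omega rho_I / rho_R,

and damping ratio ξ = (α/ω + βω)/2.

The central question this package answers numerically: **when can μ_I and
ρ_I be determined separately from motion data?** It implements

- closed-form spring-mass forward models (a mass between driven springs, the
  three-mass chain, and two-mode axial/transverse variants with a near-rigid
  bulk stiffness, relative damping factors a/b, and dilatational loss K_I);
- the *direct inversion* linear systems those measurements induce over the
  unknowns (k_R, k_I, m_I[, K_I]) with the real mass known (tissue density
  is assumed a priori equal to water);
- exact determinant-numerator polynomials (rational arithmetic) of the
  inversion submatrices, their real-root analysis, and vectorized rank
  scans — the machinery that shows, e.g., that single-frequency 1D data is
  rank 2 (ill posed), two-frequency or two-mode data is generically rank 3,
  equal mode damping ratios (b = a) collapse the rank, and adding K_I as an
  unknown removes that singularity;
- a heterogeneous 1D continuum shear solver with complex μ(x), ρ(x) and the
  RD-vs-VE *equivalence residual*: a homogeneous complex density admits an
  exactly equivalent VE medium (effective modulus μ·ρ_ref/ρ), a
  heterogeneous one does not — heterogeneous inertial damping leaves a
  measurable signature in the motion field;
- seeded synthetic-measurement generation, parameter-recovery experiments,
  and a multi-frequency power-law dispersion fit k(ω) = k_ref (ω/ω_ref)^n.

## Worked example

```python
from rdident import (RDSpringMaterial, assemble_case1, assemble_multifreq,
                     generate_measurements, numerical_rank, solve)

mat = RDSpringMaterial(kR=1.0, kI=0.1, mR=1.0, mI=-0.05)

# one frequency: ill posed
m1, = generate_measurements("I", mat, [0.7])
sys1 = assemble_case1(m1, mat.mR)
rep1 = solve(sys1)
print(rep1.rank, rep1.nullspace_basis.round(4))

# two frequencies (fixed alpha, beta): uniquely posed
m1, m2 = generate_measurements("II", mat, [0.7, 1.1])
rep2 = solve(assemble_multifreq(m1, m2, mat.mR))
print(rep2.rank, rep2.solution.round(12))
```

prints

```
2 [[-0.1056  0.7005  0.7058]]
3 [ 1.    0.1  -0.05]
```

With a single frequency the 2×3 system has rank 2: the data determine only a
one-parameter family of (k_R, k_I, m_I) triples along the printed nullspace
direction — the classical linear relation between α and β. Adding a second
frequency makes the system rank 3 and recovers the generating parameters
exactly (k_R = 1, k_I = 0.1, m_I = −0.05).

The CLI mirrors the library:

```bash
rdident forward  --case 2 --config cfg.yaml --out meas.csv
rdident invert   --case 2 --measurements meas.csv --config cfg.yaml
rdident identify --case 2 --scan "omega2=0.1:2.0:200" --config cfg.yaml
rdident continuum --profile profile.csv --omega 7.0 --rho-ref 1000
rdident experiment --spec experiment.yaml --out results/
```

## Scope

Desk-scale identifiability analysis only: no regularized or spatially
resolved reconstruction, no noise-robust inversion (noise is injected only to
report conditioning), no 2D/3D continuum solver, no poroelastic modelling.
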