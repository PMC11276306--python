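# Methods

## Model and assumptions

The package decomposes information in a jointly Gaussian system
Z = (X₁, X₂, X₃) with block dimensions (n₁, n₂, n₃). Two assumptions are
structural:

1. **Gaussianity.** All mutual informations and KL divergences are evaluated
   in closed form from log-determinants; nothing here applies to
   non-Gaussian data beyond the usual Gaussian-copula caveats.
2. **Standardisation suffices.** The KL divergence between two partitioned
   Gaussians that share mean vector and diagonal covariance blocks depends
   only on the cross-correlation blocks P = Σ₁₁^{-1/2} Σ₁₂ Σ₂₂^{-1/2} (and
   likewise Q, R). Every input — covariance file, raw data table or
   synthetic parameters — is therefore reduced to (P, Q, R) before any
   information quantity is computed. Means are estimated only to centre the
   sample covariance; they never enter a formula.

The decomposition itself follows the information-geometric recipe: project
the full distribution onto the conditional-independence submanifolds S₅
(precision block K₂₃ = 0) and S₆ (K₁₃ = 0), connect the projections by the
e-geodesic Σₜ⁻¹ = (1−t)Σ₅⁻¹ + tΣ₆⁻¹, and minimise g(t) = D(p‖pₜ). Synergy
is the minimum divergence, shared information is read off the target-block
determinant d(t) at the optimum, and the unique informations follow from
the consistency equations. The minimum-MI baseline defines shared
information as min(I[X₁;X₃], I[X₂;X₃]) instead and derives the rest from
the same equations; it always zeroes at least one unique component.

## Orientation of the determinant d(t)

Two textually circulating conventions disagree on whether the quadratic
weights (1−t)² and t² in d(t) attach to QᵀQ or to RᵀR. The package uses

    d(t) = |I − t² QᵀQ − t(1−t)(RᵀPᵀQ + QᵀPR) − (1−t)² RᵀR|,

the orientation fixed by the identity |(1−t)Σ₆ + tΣ₅| = |I − PᵀP| · d(t):
the covariance mixture at t = 0 is Σ₆, whose determinant is
|I − PᵀP||I − RᵀR|, so d(0) = |I − RᵀR| and d(1) = |I − QᵀQ|. The opposite
orientation fails that identity and produces negative shared information on
systems lying exactly on S₅ or S₆; the test suite asserts the factorisation
on random systems. The same class of check fixes the Gaussian KL trace
convention: D(N(0,A)‖N(0,B)) = ½[log(|B|/|A|) − m + tr(B⁻¹A)], validated
against the generalized Pythagorean identities
D(p‖p₅) = D(p‖p_{t*}) + D(p_{t*}‖p₅) (and the S₆ analogue), which hold
only under this convention.

## Numerical choices

- **Positive definiteness** is decided by Cholesky success after
  symmetrisation (A ← (A+Aᵀ)/2); no eigenvalue clipping is ever applied to
  inputs. Log-determinants come from Cholesky factors, so every
  log-determinant doubles as a PD certificate at the point of use.
- **Matrix square roots** in standardisation use the symmetric PD root via
  eigendecomposition (not Cholesky), so the result is basis-consistent and
  exactly symmetric.
- **Feasible interval.** F = {t : (1−t)Σ₅⁻¹ + tΣ₆⁻¹ ≻ 0} is computed from
  the generalized eigenvalues λ of (Σ₆⁻¹ − Σ₅⁻¹, Σ₅⁻¹): feasibility is
  1 + tλ > 0 for all λ, giving a closed interval [−1/λ_max, −1/λ_min] ⊇
  [0, 1]. The same interval is recomputed from the covariance-mixture
  pencil as a cross-check (the two sets provably coincide) and confirmed by
  Cholesky just inside each endpoint. A side with no eigenvalue of the
  needed sign is unbounded and capped at ±10⁶ for bracketing.
- **Optimisation.** Bounded derivative-free scalar minimisation (SciPy's
  Brent-style `bounded` method) on the interval shrunk by a relative margin
  of 10⁻⁹, convergence tolerance 10⁻¹² in t, iteration cap 1000. Strict
  convexity of g for positive joint MI justifies the single local search.
  Interior optima are certified by the stationarity traces
  tr(Σ₅⁻¹Σ_{t*}) = tr(Σ₆⁻¹Σ_{t*}) = m (tolerance 10⁻⁵·m); if the search
  touches a shrunken endpoint, g is re-evaluated at both ends, the smaller
  is kept and the result flagged `at_endpoint`. Whether a true endpoint
  minimum can occur for a PD system with positive joint MI is left open;
  the flag reports it rather than deciding.
- **Degeneracy.** Joint MI below 10⁻¹² nats (equivalently Q ≈ 0 ≈ R, where
  Σ₅ = Σ₆ and the geodesic collapses) returns the all-zero decomposition
  without optimisation.
- **Negative residues.** Components in [−10⁻⁸, 0) are clipped to zero;
  anything more negative raises, since it indicates a broken optimum rather
  than roundoff.
- **Units.** Nats internally; `in_bits()` / `--units bits` rescales
  components only. Percentages of the joint MI are base-invariant.

## The synthetic generator and what the studies show

`EquiCorrParams` fills each cross block with a constant (rank-one blocks
p·11ᵀ, q·11ᵀ, r·11ᵀ); the benchmark instance uses
(p, q, r) = (−0.15, 0.15, 0.15) with blocks (3, 4, 3), and study data are
drawn as i.i.d. zero-mean Gaussian samples of size 1000 per dataset,
1000 replicates by default (the bundled acceptance run uses 200 replicates
to keep the recomputation quick; medians at 200 are stable to well under a
percentage point, as the disjoint-seed test verifies). Covariances are
estimated with mean-centring and the unbiased n−1 divisor — the divisor
choice is irrelevant after standardisation, and is recorded in the study
metadata. Replicate seeds are spawned from the study seed via
`numpy.random.SeedSequence`, so studies are reproducible and replicates
independent.

This generator emulates exchangeable within-block correlation structure
with exact Gaussianity and i.i.d. sampling. It does not emulate heavy
tails, temporal dependence, heteroscedastic blocks or model misspecification,
so passing studies demonstrate correctness of the estimator pipeline and
the decomposition under the stated model — not robustness of the PID to
non-Gaussian real data. t\* values outside [0, 1] occur legitimately for
data generated near S₅/S₆ and are retained and counted
(`t_star["n_outside_unit"]`), not censored.

## Design choices

- Projections use the closed-form covariances of the seven submanifolds
  rather than a generic iterative information projection; the zero
  precision blocks of each projection are the acceptance check. The S₇
  source block is QRᵀ.
- The feasible interval is computed spectrally, not by bisection.
- The property suite tests the two-source consequences of the
  Williams–Beer axioms (non-negativity; self-redundancy via
  Unq_k + Shd = I[X_k;X₃]; source-exchange symmetry; and the monotonicity
  surrogate Shd ≤ min(I[X₁;X₃], I[X₂;X₃]), i.e. geometric shared
  information never exceeds the minimum-MI shared information) rather than
  the general redundancy-lattice axiom, which has no extra content for two
  sources.
- The CLI is a thin layer over the library; matrix files are headerless
  full-square CSV/TSV with block sizes supplied externally, keeping the
  format unambiguous.

## Limitations

- Exactly two source blocks; no multi-source lattice.
- No decomposition for discrete or non-Gaussian variables.
- The dependency-based PID (Idep) is out of scope; only the geometric and
  minimum-MI methods are provided.
- Near-singular inputs (|correlation| → 1) fail fast with a PD error
  rather than being regularised; callers who want shrinkage must apply it
  before input.
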