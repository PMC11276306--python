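# igpid — information-geometric partial information decomposition for Gaussian systems

`igpid` decomposes the joint mutual information that two vector sources
**X₁** (dim n₁) and **X₂** (dim n₂) carry about a vector target **X₃**
(dim n₃) of a multivariate Gaussian into four nonnegative parts:

- **Unq₁, Unq₂** — information each source carries about the target that the
  other does not;
- **Shd** — information both sources carry (redundancy);
- **Syn** — information available only from the sources jointly.

These satisfy the Williams–Beer consistency equations
I[X₁;X₃] = Unq₁ + Shd, I[X₂;X₃] = Unq₂ + Shd,
I[X₁;X₃|X₂] = Unq₁ + Syn, I[X₂;X₃|X₁] = Unq₂ + Syn, and
I[X₁,X₂;X₃] = Syn + Unq₁ + Unq₂ + Shd.
Typical users are researchers in systems biology and network neuroscience
who ask whether a response variable is driven redundantly, uniquely or
synergistically by two groups of predictors.

## The method

Every computation happens on the standardised covariance

    Σ = [[I, P, Q], [Pᵀ, I, R], [Qᵀ, Rᵀ, I]],

where P, Q, R are the pairwise cross-correlation blocks — Gaussian KL
divergences between distributions sharing diagonal blocks depend on nothing
else, so means and block scales are irrelevant. Zeroing an off-diagonal
block of the precision matrix K = Σ⁻¹ encodes a conditional independence;
the two key model submanifolds are S₅ (K₂₃ = 0, target independent of
source 2 given source 1) and S₆ (K₁₃ = 0), whose m-projections have
closed-form covariances Σ₅ = (P, Q, PᵀQ) and Σ₆ = (P, PR, R).

The e-geodesic between the projections interpolates precisions linearly,
Σₜ⁻¹ = (1−t)Σ₅⁻¹ + tΣ₆⁻¹, and the synergy objective g(t) = D(p‖pₜ) is
strictly convex on the feasible interval F = {t : Σₜ ≻ 0} whenever the
joint MI is positive, so the minimiser t\* is unique and found by bounded
scalar minimisation. With the target-block determinant

    d(t) = |I − t²QᵀQ − t(1−t)(RᵀPᵀQ + QᵀPR) − (1−t)²RᵀR|

the components are

    Shd  = ½ log(1/d(t*))          Unq₁ = I[X₁;X₃] − Shd
    Syn  = D(p ‖ p_{t*})           Unq₂ = I[X₂;X₃] − Shd.

A minimum-mutual-information baseline (`pid_mmi`), in which
Shd = min(I[X₁;X₃], I[X₂;X₃]), is included for comparison.

## Worked example

The benchmark system fills each cross-correlation block with a constant:
(p, q, r) = (−0.15, 0.15, 0.15) with blocks (3, 4, 3), a 10-dimensional
Gaussian. From the shell:

```sh
igpid pid --pqr -0.15,0.15,0.15 --blocks 3,4,3 --methods iig
```

prints (abridged):

```json
{
  "method": "iig",
  "components": {"syn": 1.7177, "unq1": 0.0844, "unq2": 0.1287, "shd": 0.0287},
  "percentages": {"unq1": 4.31, "unq2": 6.57, "shd": 1.46, "syn": 87.66},
  "t_star": 0.5472,
  "mi": {"i13": 0.1131, "i23": 0.1574, "joint": 1.9594},
  "diagnostics": {"feasible_interval": [-0.6016, 1.6959]}
}
```

Read: the system transmits 1.96 nats jointly, of which 87.7% is synergy —
the two weakly target-correlated source groups (I[X₁;X₃] ≈ 0.11 nats,
I[X₂;X₃] ≈ 0.16 nats) are jointly far more informative than separately,
driven by the negative inter-source correlation. The geodesic optimum sits
at t\* ≈ 0.547 inside the feasible interval (−0.60, 1.70).

The same decomposition is available in Python:

```python
from igpid import BENCHMARK, equicorr_system, pid_ig, as_percentages
res = pid_ig(equicorr_system(BENCHMARK))
print(res.t_star, as_percentages(res))   # (unq1, unq2, shd, syn) in %
```

Other entry points: `igpid pid --cov matrix.csv --blocks n1,n2,n3` for a
covariance file, `--data table.csv` for raw samples, `--submanifold 5` to
project the input first, `igpid simulate` for replication studies and
`igpid fixtures` to write the benchmark covariances to disk.

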