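# Methods

## Model

Each variant j = 1, …, J observed in K cohorts carries a latent
configuration vector H_j ∈ {−1, 0, +1}^K: cohort k's association status
(negative, null, positive). The replication composite null is the set ℋ₀ of
all configurations except the two same-sign vectors (all +1, all −1), which
form the alternative ℋ_a. `enumerate_configurations` lists the 3^K
configurations canonically: binary non-null patterns in lexicographic order,
then sign assignments within a pattern with −1 before +1 (for K = 2:
(0,0), (0,−1), (0,+1), (−1,0), (+1,0), (−1,−1), (−1,+1), (+1,−1), (+1,+1)).
K is capped at 8 since every variant's lfdr sums over all 3^K terms.

The observed z-statistics are modelled by a two-group mixture that
factorizes over cohorts given the configuration:

* null cohort (h_k = 0): standard normal. The theoretical null is retained;
  no empirical-null recalibration is attempted.
* non-null cohort (h_k = s): an M-component Gaussian mixture with weights
  λ_km, locations s·μ_km (μ_km > 0) and variances τ²_km ≥ 1.

The prior over configurations is parameterized by one weight w_b per binary
non-null pattern b ∈ {0,1}^K, split equally over the 2^|b| sign patterns
sharing b. This equal split plus the variance floor τ² ≥ 1 are the
*conditional symmetry* constraints: together they guarantee the lfdr,

    lfdr_j = Σ_{ℋ₀} Pr(h) f(z_j|h) / Σ_{all} Pr(h) f(z_j|h),

is non-increasing in each |z_jk| along same-sign directions, so Bayesian
replication rankings can never contradict the frequentist ordering of
same-sign z-vectors. The test suite verifies this monotonicity on a dense
two-cohort grid and on random three-cohort rays rather than relying on the
algebra alone.

Variants are ranked by lfdr and the longest ascending prefix whose running
mean stays at or below the nominal level q is rejected (ties broken by input
index for determinism). The running mean of rejected lfdr values estimates
the Bayes FDR of the rejection set.

## Estimation

`fit_em` maximizes the observed-data likelihood by EM over the complete-data
labels (configuration, per-cohort mixture component):

* **E-step.** Configuration responsibilities r_jl ∝ Pr(h_l) f(z_j | h_l),
  computed in log space with log-sum-exp throughout.
* **M-step.** w_b is the mean responsibility pooled over all sign patterns
  of pattern b (the symmetry constraint makes this the constrained
  maximizer). Per cohort, the +1 and −1 responsibilities are pooled on
  reflected data (x = s·z), giving closed-form updates for λ_km, μ_km and
  τ²_km; μ is kept positive (floor 10⁻³) and τ² is floored at 1. Both floors
  are constrained maximizers, so the likelihood ascent property is
  preserved; the suite asserts a non-decreasing log-likelihood trace.

Initialization is a deterministic method-of-moments start: per cohort, the
component locations are quantiles of |z| above 2 (spaced slightly apart when
they coincide), uniform λ, τ² = 1, and a small symmetric prior mass of 10⁻⁴
on every non-null binary pattern. Convergence is declared when the relative
log-likelihood change drops below `tol` (default 10⁻⁶), with `max_iter` 500;
non-convergence produces a warning and a flagged fit, not an error. A
degenerate all-identical input returns the initial fit flagged
non-converged. Fitting refuses inputs with NaNs and inputs shorter than
`min_variants` (default 10,000 — mixture estimates on shorter panels are too
unstable to be meaningful).

Defaults that matter:

| parameter | default | meaning |
|---|---|---|
| M | 2 | mixture components per cohort; 1 suffices for single-mode signals, 2 adds robustness to heterogeneous effect sizes |
| q | 0.1 | nominal FDR of the rejection rule |
| tol | 1e-6 | relative log-likelihood convergence threshold |
| max_iter | 500 | EM iteration cap |
| τ² floor | 1 | alternatives no tighter than the null (part of the no-contradiction guarantee) |

The alternative mixture is fitted per cohort rather than shared across
cohorts. This is a deliberate design choice: cohorts differ widely in sample
size and hence in signal strength, and a per-cohort magnitude distribution
lets the model adapt to, say, one well-powered and one marginal cohort
without inflating either.

## Comparators

* **Meta-analysis** combines z-statistics with weights √N_k:
  z_meta = Σ √N_k z_k / √(Σ N_k); two-sided p; significance at α (default
  10⁻⁸). For case-control cohorts the effective sample size
  4/(1/n_cases + 1/n_controls) should be supplied as N_k. Meta-analysis
  tests the global null, so it is expected to over-reject as a replication
  criterion — that failure mode is the point of including it.
* **Threshold rule** flags a variant when every cohort's p-value is below t.
  Sign consistency across cohorts is required by default (a variant with
  opposite directions should not count as replicated); a switch disables it
  to reproduce the laxer variant.

## Synthetic data

`generate_truth` draws each cohort's causal indicators independently across
cohorts and variants at that cohort's causal proportion, then splits each
realized causal set exactly in half between + and − effects (odd counts
differ by one, the extra sign randomized). The exact half-split follows the
balanced-signs design literally rather than using independent fair coins;
at the simulated scales the difference is negligible. Signs are independent
across cohorts, which makes opposite-sign overlaps part of the null, as the
composite null requires. `generate_z` draws z_jk ~ Normal(H_jk·μ, sd²) with
sd = 1 by default (z-statistics); all generation is deterministic given a
seed.

Consequences used by the tests: expected causal count per cohort is π_k·J;
the expected fraction causal in all cohorts is Π π_k; with balanced
independent signs the truly-replicated fraction is Π π_k · 2/2^K.

`generate_sumstats_fixture` emits raw per-cohort summary tables (SNP, CHR,
BP, A1, A2, BETA, SE, P, N) sharing a variant backbone, with a configurable
fraction of allele flips (alleles swapped, effect negated) in non-reference
cohorts and a fraction of cohort-private variants, including strand-ambiguous
A/T and C/G pairs. The generator records its internal truth so harmonization
can be checked for exact sign recovery.

What the generator does **not** emulate: linkage disequilibrium between
variants, cross-cohort correlation of noise or of causal status, genotype- or
phenotype-level sampling, allele-frequency structure, and imputation
artifacts. Passing tests therefore demonstrate calibration and power under
independence; on real data, LD will spread signals across correlated
variants and the realized FDR is with respect to statistical — not
biological — replication of each individual variant.

## Harmonization

Variants are matched on chromosome:position:unordered-allele-pair, not rsID
(IDs drift across builds; the rsID is kept as annotation). Coordinates are
1-based. The first cohort fixes the orientation; a cohort reporting the
swapped allele pair has its effect sign negated and is flagged. Duplicate
keys within a cohort keep the smallest-SE record. Strand-ambiguous A/T and
C/G pairs are retained but flagged, with an option to exclude them
(frequency-based strand resolution is out of scope). z is taken as beta/SE
where available; the p+direction dialect reconstructs z = sign ·
Φ⁻¹(1 − p/2) as a fallback only, to avoid p-value rounding artifacts.
No MAF or imputation-quality filtering is applied at this stage.

## Evaluation conventions

Per replicate, a method's false discovery proportion is FP/max(R, 1) and its
power is TP over the number of truly replicated variants in that replicate
(undefined and reported missing when there are none). Empirical FDR and
power are means over replicates with Monte-Carlo standard errors; this
per-replicate-then-average convention is the standard one in the two-group
literature. Replicate seeds are spawned from the cell seed via
`numpy.random.SeedSequence`; grid cells use seed XOR cell-index, so any cell
and the whole grid are reproducible from one master seed.

Problem sizes: the default desk-scale profile used by the acceptance
computation and the test suite is J = 100,000 variants with 20 replicates
for the calibration cell, and J = 50,000 with 8 replicates per cell for the
directional method-comparison grid — sizes chosen so each cell contains a
meaningful number of truly replicated variants while the whole suite runs in
a few minutes on one CPU. Genome-scale runs (millions of variants, 100
replicates) use the same code paths; memory for the J × 3^K responsibility
matrix is the only practical constraint.

## Numerical choices

All density sums run in log space via log-sum-exp; lfdr values are clipped
to [0, 1] after exponentiation. Zero pattern weights are admissible (the
corresponding configurations simply drop out; EM cannot revive an exactly
zero weight, which is standard). The rejection rule's stable sort makes
results independent of input order up to ties.

## Limitations

* The composite null is all-or-nothing: partial replication ("non-null in at
  least m of K cohorts") is not supported.
* Variants are treated as independent; no LD-aware priors or pruning.
* The theoretical N(0,1) null is assumed correct; confounding that inflates
  null z-statistics (population stratification, uncorrected relatedness)
  will inflate the realized FDR.
* K is limited to 8 by the 3^K configuration sum.
* Liftover between genome builds and allele-frequency-based strand
  resolution are out of scope for harmonization.
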