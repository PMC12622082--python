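# replimix

Model-based replication testing for GWAS summary statistics.

## The problem

A variant counts as *replicated* across K GWAS cohorts only when its effect
is non-zero **and** points in the same direction in every cohort. The
hypothesis actually being tested is therefore a *composite null*: for
per-cohort regression coefficients θ₁, …, θ_K,

    H₀ : (θ_k = 0 for some k)  ∪  (sign(θ_k) ≠ sign(θ_k') for some k ≠ k').

The two approaches commonly used to integrate multiple GWAS both miss this
target. Meta-analysis tests the *global* null (θ₁ = … = θ_K = 0) — a single
point inside the composite null — so a strong signal in one cohort can reach
significance without replicating anywhere else. Requiring a fixed p-value
cutoff in every cohort does test the composite null, but it is not
data-adaptive and detects almost nothing when any cohort is underpowered.

`replimix` implements a formal empirical-Bayes test of the composite null.
Each variant j carries a latent configuration vector
H_j ∈ {−1, 0, +1}^K giving its association status per cohort; exactly two of
the 3^K configurations (all +1, all −1) form the alternative. The package is
aimed at statistical geneticists who have harmonized per-cohort summary
statistics (or want to harmonize them — that stage is included) and want a
calibrated, interpretable replication decision per variant.

## The model

For z-statistics z_j = (z_j1, …, z_jK) the two-group model is

    lfdr_j = Pr(H_j ∈ ℋ₀ | Z_j = z_j)
           = Σ_{l: h_l ∈ ℋ₀} f(z_j | H_j = h_l) Pr(H_j = h_l)
             ───────────────────────────────────────────────
             Σ_{l=0}^{L}     f(z_j | H_j = h_l) Pr(H_j = h_l)

with f a product over cohorts: a standard normal where h_lk = 0 and an
M-component Gaussian mixture with positive locations μ_km (reflected to the
sign of h_lk) where it is non-null. Two constraints make the mixture
*conditionally symmetric* and provably prevent frequentist–Bayesian ranking
contradictions (a variant with componentwise larger same-sign |z| can never
look less replicated):

* all sign patterns sharing a binary non-null pattern get equal prior mass;
* alternative component variances are floored at the null variance, τ² ≥ 1.

Priors and mixture parameters are estimated from all J variants jointly by a
constrained EM algorithm. Sorting variants by lfdr and rejecting the longest
prefix whose running mean stays ≤ q controls the false discovery rate at q
(default q = 0.1).

The baselines are included as comparators: sample-size-weighted
meta-analysis, z_meta = Σ_k √N_k z_k / √(Σ_k N_k) (Stouffer's method for
equal N, with the case-control effective sample size 4/(1/n_cases +
1/n_controls)), and the multi-cohort p-value threshold rule with optional
sign-consistency.

## Worked example

Two cohorts of 100,000 variants, 2% causal in each cohort independently with
balanced ± signs, causal z-statistic mean 5. With independent causal
assignment only ~0.02% of variants (≈ 20) are causal in both cohorts with
matching signs — the truly replicated set.

```python
import numpy as np
import replimix as rm

config = rm.SimulationConfig(
    J=100_000, K=2, causal_proportions=(0.02, 0.02), effect_mean=5.0, seed=7
)
truth = rm.generate_truth(config, seed=7)
Z = rm.generate_z(truth, config.effect_mean, seed=8)

fit, res = rm.replication_analysis(Z, q=0.1)
print(f"EM converged in {fit.n_iter} iterations")
print(f"estimated replicated-pattern prior mass: {fit.pattern_weights[3]:.2e}")
print(f"{res.n_rejected} variants rejected at nominal FDR 0.1")
tp = int((res.rejected & truth.replicated).sum())
print(f"{tp} of {int(truth.replicated.sum())} truly replicated variants recovered, "
      f"{res.n_rejected - tp} false discoveries")

meta = rm.meta_analyze(Z, np.ones(2), alpha=1e-8)
fp_meta = int((meta.significant & ~truth.replicated).sum())
print(f"meta-analysis flags {int(meta.significant.sum())} variants, "
      f"{fp_meta} not truly replicated")
P = rm.z_to_p(Z)
thr = rm.threshold_rule(P, np.sign(Z), 1e-8)
tp_thr = int((thr.significant & truth.replicated).sum())
print(f"threshold rule (p<1e-8 in both) flags {int(thr.significant.sum())} "
      f"variants, {tp_thr} true")
```

Output:

```
EM converged in 8 iterations
estimated replicated-pattern prior mass: 4.39e-04
29 variants rejected at nominal FDR 0.1
27 of 27 truly replicated variants recovered, 2 false discoveries
meta-analysis flags 81 variants, 55 not truly replicated
threshold rule (p<1e-8 in both) flags 2 variants, 2 true
```

The estimated prior mass of the replicated pattern (4.39 × 10⁻⁴) matches the
design value 0.02² = 4 × 10⁻⁴. The model-based test recovers all 27 truly
replicated variants at a realized false discovery proportion of 2/29 ≈ 0.07,
within its nominal 0.1. Meta-analysis flags three times as many variants,
two thirds of them not replicated — the global-null failure mode — while the
threshold rule finds only the 2 most extreme signals.

## Command line

Each subcommand is a thin wrapper over the library:

```bash
replimix harmonize cohortA.tsv cohortB.tsv --out panel.parquet
replimix replicate --panel panel.parquet --q 0.1 --out replication.tsv
replimix meta      --panel panel.parquet --alpha 1e-8 --out meta.tsv
replimix threshold --panel panel.parquet --t 1e-8 --out threshold.tsv
replimix simulate  --config grid.yaml --out metrics.tsv --plot curves.png
replimix evaluate  --flags replication.tsv --truth truth.tsv
```

`harmonize` intersects cohorts on chromosome:position:allele-pair keys,
flips effect signs where a cohort reports the opposite effect allele, flags
strand-ambiguous A/T and C/G pairs, and writes the z-matrix panel that the
testing subcommands consume.

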