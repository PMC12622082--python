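"""Simulation experiments: empirical FDR and power of the three decision rules.

Each cell of the experiment grid fixes (mean effect size, per-cohort causal
proportions, K).  Per replicate, a truth matrix and z-matrix are generated,
the model-based replication test (EM fit + lfdr + cumulative-mean rejection
at the nominal FDR), the sample-size-weighted meta-analysis, and the p-value
threshold rule are applied, and each method's discoveries are scored against
the truly-replicated labels.  Per replicate the false discovery proportion is
FP / max(R, 1) and power is TP over the number of truly replicated variants
(undefined when there are none); both are averaged over replicates with
Monte-Carlo standard errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import comparators, model, simulate

__all__ = ["score_flags", "run_cell", "grid_run", "plot_metrics"]

DEFAULT_THRESHOLDS = (1e-8, 1e-5)


def score_flags(flags: np.ndarray, replicated: np.ndarray) -> dict:
    """Score one method's rejection set against the truly-replicated labels."""
    flags = np.asarray(flags, dtype=bool)
    replicated = np.asarray(replicated, dtype=bool)
    if flags.shape != replicated.shape:
        raise ValueError("flags and truth labels must align")
    R = int(flags.sum())
    TP = int((flags & replicated).sum())
    FP = R - TP
    n_true = int(replicated.sum())
    return {
        "discoveries": R,
        "tp": TP,
        "fp": FP,
        "n_replicated": n_true,
        "fdp": FP / max(R, 1),
        "power": TP / n_true if n_true > 0 else np.nan,
    }


def _rep_rngs(seed, n_reps: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_reps)]


def run_cell(
    config: simulate.SimulationConfig,
    seed=None,
    methods=("replication", "meta", "threshold"),
    thresholds=DEFAULT_THRESHOLDS,
    meta_alpha: float = 1e-8,
    em_kwargs: dict | None = None,
    return_reps: bool = False,
):
    """Run all replicates of one simulation cell and aggregate metrics.

    Returns a long-format DataFrame with one row per (method, parameter):
    empirical FDR and power with Monte-Carlo SEs over replicates.  With
    ``return_reps`` the per-replicate scores are returned as well.
    """
    em_kwargs = dict(em_kwargs or {})
    seed = config.seed if seed is None else seed
    rows = []
    for rep, rng in enumerate(_rep_rngs(seed, config.n_reps)):
        truth = simulate.generate_truth(config, seed=rng)
        Z = simulate.generate_z(truth, config.effect_mean, config.effect_sd, seed=rng)
        if "replication" in methods:
            _, res = model.replication_analysis(Z, q=config.nominal_fdr, **em_kwargs)
            rows.append(
                {"method": "replication", "param": config.nominal_fdr, "rep": rep}
                | score_flags(res.rejected, truth.replicated)
            )
        if "meta" in methods:
            meta = comparators.meta_analyze(Z, np.ones(config.K), alpha=meta_alpha)
            rows.append(
                {"method": "meta", "param": meta_alpha, "rep": rep}
                | score_flags(meta.significant, truth.replicated)
            )
        if "threshold" in methods:
            P = comparators.z_to_p(Z)
            for t in thresholds:
                thr = comparators.threshold_rule(P, np.sign(Z), t)
                rows.append(
                    {"method": "threshold", "param": t, "rep": rep}
                    | score_flags(thr.significant, truth.replicated)
                )
    reps = pd.DataFrame(rows)
    summary = _summarize(reps, config)
    return (summary, reps) if return_reps else summary


def _sem(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if x.size <= 1:
        return np.nan
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def _summarize(reps: pd.DataFrame, config: simulate.SimulationConfig) -> pd.DataFrame:
    out = []
    for (method, param), g in reps.groupby(["method", "param"], sort=False):
        fdp = g["fdp"].to_numpy(dtype=float)
        power = g["power"].to_numpy(dtype=float)
        out.append(
            {
                "method": method,
                "param": param,
                "mu": config.effect_mean,
                "proportions": "/".join(f"{p:g}" for p in config.causal_proportions),
                "K": config.K,
                "J": config.J,
                "n_reps": len(g),
                "fdr": float(np.mean(fdp)),
                "fdr_se": _sem(fdp),
                "power": float(np.nanmean(power)) if np.any(~np.isnan(power)) else np.nan,
                "power_se": _sem(power),
                "mean_discoveries": float(g["discoveries"].mean()),
            }
        )
    return pd.DataFrame(out)


def grid_run(
    mus,
    proportions,
    Ks,
    J: int,
    n_reps: int,
    seed: int = 0,
    q: float = 0.1,
    effect_sd: float = 1.0,
    methods=("replication", "meta", "threshold"),
    thresholds=DEFAULT_THRESHOLDS,
    meta_alpha: float = 1e-8,
    em_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Cross-product over (mu, proportions, K) cells with derived seeds.

    ``proportions`` entries may be scalars (shared by all cohorts of a cell)
    or per-cohort tuples matched to K.  Cell seeds are seed XOR cell-index,
    so cells are independent and the whole grid is reproducible.
    """
    frames = []
    cell = 0
    for K in np.atleast_1d(Ks):
        for pi in proportions:
            pis = tuple(np.broadcast_to(np.asarray(pi, dtype=float), (int(K),)))
            for mu in np.atleast_1d(mus):
                config = simulate.SimulationConfig(
                    J=int(J),
                    K=int(K),
                    causal_proportions=pis,
                    effect_mean=float(mu),
                    effect_sd=effect_sd,
                    n_reps=int(n_reps),
                    seed=int(seed) ^ cell,
                    nominal_fdr=q,
                )
                frames.append(
                    run_cell(
                        config,
                        methods=methods,
                        thresholds=thresholds,
                        meta_alpha=meta_alpha,
                        em_kwargs=em_kwargs,
                    )
                )
                cell += 1
    return pd.concat(frames, ignore_index=True)


def plot_metrics(results: pd.DataFrame, q: float = 0.1):
    """FDR and power versus mean effect size, one line per method/parameter.

    One pair of panels per (K, proportions) setting, with the nominal FDR as
    a horizontal reference line in the FDR panel.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    settings = list(results.groupby(["K", "proportions"], sort=True).groups)
    fig, axes = plt.subplots(
        len(settings), 2, figsize=(9, 3.2 * len(settings)), squeeze=False
    )
    for i, (K, props) in enumerate(settings):
        block = results[(results["K"] == K) & (results["proportions"] == props)]
        for (method, param), g in block.groupby(["method", "param"], sort=False):
            label = method if method != "threshold" else f"threshold {param:g}"
            g = g.sort_values("mu")
            axes[i, 0].errorbar(g["mu"], g["fdr"], yerr=g["fdr_se"], label=label, marker="o")
            axes[i, 1].errorbar(g["mu"], g["power"], yerr=g["power_se"], label=label, marker="o")
        axes[i, 0].axhline(q, color="gray", lw=1)
        axes[i, 0].set_ylabel(f"FDR (K={K}, pi={props})")
        axes[i, 1].set_ylabel("power")
        for ax in axes[i]:
            ax.set_xlabel("mean effect size")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    return fig
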