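"""Real-data-style summaries: method-overlap tables and Manhattan plots.

The overlap table anchors on each cohort's GWAS-significant variants
(p < 5e-8 by convention) and reports what percentage of them each decision
rule flags, plus total flagged counts.  The Manhattan plot displays variants
below a p-value display floor, colored red when flagged by both the
replication test and meta-analysis, green for meta-analysis only and blue
for replication only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["overlap_table", "manhattan", "GWAS_ALPHA"]

GWAS_ALPHA = 5e-8


def overlap_table(
    pvalues: np.ndarray,
    method_flags: dict,
    cohorts: list | None = None,
    gwas_alpha: float = GWAS_ALPHA,
    pair: tuple = ("replication", "meta"),
) -> pd.DataFrame:
    """Percentage of each cohort's GWAS-significant variants flagged per method.

    ``method_flags`` maps method name to a boolean flag vector aligned with
    the rows of ``pvalues``.  Rows: the GWAS-significant count per cohort,
    one row per method, and the intersection of ``pair`` (replication and
    meta-analysis by default).  The ``total`` column holds raw flagged
    counts; all percentages are recomputable from it and the per-cohort
    anchor counts.
    """
    P = np.atleast_2d(np.asarray(pvalues, dtype=float))
    J, K = P.shape
    cohorts = list(cohorts) if cohorts is not None else [f"cohort{k}" for k in range(K)]
    if len(cohorts) != K:
        raise ValueError("one cohort name per p-value column required")
    flags = {}
    for name, f in method_flags.items():
        f = np.asarray(f, dtype=bool)
        if f.shape != (J,):
            raise ValueError(f"flags for {name!r} are misaligned with the panel")
        flags[name] = f
    if pair is not None and all(m in flags for m in pair):
        flags[" + ".join(pair)] = flags[pair[0]] & flags[pair[1]]

    gwas_sig = P < gwas_alpha
    rows = [
        {
            "row": f"GWAS significant (p < {gwas_alpha:g})",
            **{c: int(gwas_sig[:, k].sum()) for k, c in enumerate(cohorts)},
            "total": int(np.any(gwas_sig, axis=1).sum()),
        }
    ]
    for name, f in flags.items():
        row = {"row": name}
        for k, c in enumerate(cohorts):
            n_anchor = int(gwas_sig[:, k].sum())
            row[c] = 100.0 * (f & gwas_sig[:, k]).sum() / n_anchor if n_anchor else np.nan
        row["total"] = int(f.sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("row")


def manhattan(
    chrom,
    pos,
    pvalues,
    replication_flags,
    meta_flags,
    p_display_floor: float = 1e-4,
    ax=None,
):
    """Manhattan plot of -log10(p) with three-color method-significance overlay.

    Only variants with p below the display floor appear.  Returns (fig, ax);
    the inputs are not modified.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    rep = np.asarray(replication_flags, dtype=bool)
    meta = np.asarray(meta_flags, dtype=bool)
    if not (len(chrom) == len(pos) == len(p) == len(rep) == len(meta)):
        raise ValueError("all inputs must have the same length")

    # cumulative genomic coordinate, chromosome blocks laid end to end
    x = np.empty(len(pos))
    offset = 0.0
    order = pd.unique(chrom)
    for c in order:
        m = chrom == c
        x[m] = pos[m] + offset
        offset += pos[m].max() + 1.0 if m.any() else 0.0

    shown = p < p_display_floor
    y = -np.log10(np.clip(p, np.finfo(float).tiny, None))
    groups = [
        ("lightgray", shown & ~rep & ~meta, "not flagged"),
        ("green", shown & meta & ~rep, "meta-analysis only"),
        ("blue", shown & rep & ~meta, "replication only"),
        ("red", shown & rep & meta, "replication + meta"),
    ]
    if ax is None:
        fig, ax = plt.subplots(figsize=(9, 3))
    else:
        fig = ax.figure
    for color, mask, label in groups:
        ax.scatter(x[mask], y[mask], s=6, c=color, label=label, rasterized=True)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("-log10(p)")
    ax.legend(fontsize=7, markerscale=2)
    return fig, ax
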