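"""Align multi-cohort GWAS summary statistics to a shared, sign-consistent panel.

Cohorts are intersected on a variant key of chromosome, position and the
unordered allele pair (rsIDs drift across builds, so they are kept only as
annotation).  Where a cohort reports the effect for the opposite allele
relative to the first cohort, its effect sign is negated; strand-ambiguous
A/T and C/G variants are flagged and optionally excluded.  The output is the
J x K z-statistic matrix consumed by the testing stages, with z = beta / SE,
or sign * inverse-normal(1 - p/2) for p-value-plus-direction inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "DIALECTS",
    "HarmonizedPanel",
    "read_sumstats",
    "canonicalize_sumstats",
    "harmonize",
    "save_panel",
    "load_panel",
]

# column mappings: canonical name -> source column
DIALECTS = {
    "fixture": {
        "snp": "SNP",
        "chrom": "CHR",
        "pos": "BP",
        "a1": "A1",
        "a2": "A2",
        "beta": "BETA",
        "se": "SE",
        "p": "P",
        "n": "N",
    },
    "regenie": {
        "snp": "ID",
        "chrom": "CHROM",
        "pos": "GENPOS",
        "a1": "ALLELE1",
        "a2": "ALLELE0",
        "beta": "BETA",
        "se": "SE",
        "log10p": "LOG10P",
        "n": "N",
    },
    # p-value plus direction of effect, no beta/SE
    "p+direction": {
        "snp": "SNP",
        "chrom": "CHR",
        "pos": "BP",
        "a1": "A1",
        "a2": "A2",
        "p": "P",
        "direction": "DIR",
        "n": "N",
    },
}

_AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}
_VALID = set("ACGT")


@dataclass
class HarmonizedPanel:
    """Cohort-aligned z-statistics on the shared variant set.

    ``variants`` holds key, chrom, pos, alleles (in the first cohort's
    orientation) and rsID; ``Z``, ``pvalues`` and ``flipped`` are J x K
    arrays aligned to it; ``ambiguous`` flags strand-ambiguous allele pairs.
    """

    variants: pd.DataFrame
    Z: np.ndarray
    N: np.ndarray
    pvalues: np.ndarray
    flipped: np.ndarray
    ambiguous: np.ndarray
    cohorts: list
    counts: dict = field(default_factory=dict)

    @property
    def J(self) -> int:
        return self.Z.shape[0]

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = self.variants.reset_index(drop=True).copy()
        for k, name in enumerate(self.cohorts):
            df[f"z_{name}"] = self.Z[:, k]
            df[f"p_{name}"] = self.pvalues[:, k]
        df["ambiguous"] = self.ambiguous
        return df


def _variant_key(chrom, pos, a1, a2) -> pd.Series:
    lo = np.minimum(a1, a2)
    hi = np.maximum(a1, a2)
    return chrom.astype(str) + ":" + pos.astype(str) + ":" + lo + ":" + hi


def read_sumstats(path, dialect: str = "fixture") -> pd.DataFrame:
    """Read one cohort's summary statistics into the canonical column layout.

    Rows violating the basic invariants (non-positive SE, p outside (0, 1],
    non-ACGT or identical alleles) are dropped with a logged count.  Returns
    columns snp, chrom, pos, a1, a2, beta, se, p, n, z (beta and se are NaN
    in the p+direction dialect, where z is reconstructed from p and the
    direction column).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    raw = pd.read_csv(path, sep=r"\s+")
    return canonicalize_sumstats(raw, dialect=dialect, label=str(path))


def canonicalize_sumstats(
    raw: pd.DataFrame, dialect: str = "fixture", label: str = "table"
) -> pd.DataFrame:
    """Validate an in-memory summary table and map it to the canonical layout."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    mapping = DIALECTS[dialect]
    path = label
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()

    if "log10p" in df.columns:
        df["p"] = np.power(10.0, -df.pop("log10p").astype(float))
    n0 = len(df)
    ok = (
        df["a1"].isin(_VALID)
        & df["a2"].isin(_VALID)
        & (df["a1"] != df["a2"])
        & df["p"].between(0.0, 1.0, inclusive="right")
        & (df["p"] > 0.0)
    )
    if "beta" in df.columns:
        ok &= np.isfinite(df["beta"]) & (df["se"] > 0.0)
        df["z"] = df["beta"] / df["se"]
    else:
        direction = df.pop("direction").astype(str)
        sign = direction.map({"+": 1.0, "-": -1.0})
        ok &= sign.notna()
        df["beta"] = np.nan
        df["se"] = np.nan
        df["z"] = sign * norm.isf(df["p"] / 2.0)
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.info("%s: dropped %d of %d rows failing validation", path, dropped, n0)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no valid rows after filtering")
    df.attrs["n_dropped_invalid"] = dropped
    return df


def _dedupe(df: pd.DataFrame, label: str) -> tuple:
    """Resolve duplicate variant keys by keeping the smallest-SE record."""
    if not df["key"].duplicated().any():
        return df, 0
    kept = (
        df.assign(_se=df["se"].fillna(np.inf))
        .sort_values(["key", "_se"], kind="mergesort")
        .drop_duplicates("key", keep="first")
        .drop(columns="_se")
        .sort_index()
    )
    n_dup = len(df) - len(kept)
    logger.info("%s: dropped %d duplicate-key rows (kept smallest SE)", label, n_dup)
    return kept, n_dup


def harmonize(
    tables: list,
    cohorts: list | None = None,
    exclude_ambiguous: bool = False,
) -> HarmonizedPanel:
    """Intersect cohorts on the variant key and align effect directions.

    The first table fixes the allele orientation.  A cohort whose effect and
    other alleles are swapped relative to it has its z negated and is flagged
    as flipped; allele pairs that cannot be reconciled are dropped and
    counted.  Output variants are sorted by chromosome, position and key.
    """
    if len(tables) < 2:
        raise ValueError("harmonize needs at least two cohorts")
    cohorts = cohorts or [f"cohort{k}" for k in range(len(tables))]
    if len(cohorts) != len(tables):
        raise ValueError("one cohort name per table required")

    counts: dict = {}
    keyed = []
    for name, df in zip(cohorts, tables):
        df = df.copy()
        df["key"] = _variant_key(df["chrom"], df["pos"], df["a1"], df["a2"])
        df, n_dup = _dedupe(df, name)
        counts[name] = {"input": len(df) + n_dup, "duplicates_dropped": n_dup}
        df = df.set_index("key", drop=False)
        df.index.name = None
        keyed.append(df)

    shared = keyed[0].index
    for df in keyed[1:]:
        shared = shared.intersection(df.index)
    if shared.empty:
        first = keyed[0].iloc[0]
        raise ValueError(
            "no variants shared across all cohorts; first key of first cohort: "
            f"{first['key']} (chrom={first['chrom']}, pos={first['pos']})"
        )

    ref = keyed[0].loc[shared]
    ref = (
        ref.assign(_ck=_chrom_sort_key(ref["chrom"]))
        .sort_values(["_ck", "pos", "key"], kind="mergesort")
        .drop(columns="_ck")
    )
    shared = ref.index

    J, K = len(shared), len(tables)
    Z = np.empty((J, K))
    P = np.empty((J, K))
    flipped = np.zeros((J, K), dtype=bool)
    N = np.empty(K)
    keep = np.ones(J, dtype=bool)

    for k, (name, df) in enumerate(zip(cohorts, keyed)):
        sub = df.loc[shared]
        same = (sub["a1"].to_numpy() == ref["a1"].to_numpy()) & (
            sub["a2"].to_numpy() == ref["a2"].to_numpy()
        )
        swap = (sub["a1"].to_numpy() == ref["a2"].to_numpy()) & (
            sub["a2"].to_numpy() == ref["a1"].to_numpy()
        )
        bad = ~(same | swap)
        if bad.any():
            logger.info("%s: dropped %d irreconcilable allele pairs", name, int(bad.sum()))
        keep &= ~bad
        z = sub["z"].to_numpy(dtype=float)
        z[swap] = -z[swap]
        Z[:, k] = z
        P[:, k] = sub["p"].to_numpy(dtype=float)
        flipped[:, k] = swap
        N[k] = float(np.nanmedian(sub["n"].to_numpy(dtype=float)))
        counts[name]["flipped"] = int(swap.sum())
        counts[name]["irreconcilable"] = int(bad.sum())

    pair = ref["a1"].to_numpy().astype(object)
    ambiguous = np.array(
        [frozenset((x, y)) in _AMBIGUOUS_PAIRS for x, y in zip(pair, ref["a2"])]
    )
    if exclude_ambiguous:
        counts["ambiguous_excluded"] = int((ambiguous & keep).sum())
        keep &= ~ambiguous

    variants = pd.DataFrame(
        {
            "key": ref["key"].to_numpy(),
            "chrom": ref["chrom"].to_numpy(),
            "pos": ref["pos"].to_numpy(),
            "a1": ref["a1"].to_numpy(),
            "a2": ref["a2"].to_numpy(),
            "rsid": ref["snp"].to_numpy(),
        }
    )[keep].reset_index(drop=True)
    counts["shared"] = int(keep.sum())

    panel = HarmonizedPanel(
        variants=variants,
        Z=Z[keep],
        N=N,
        pvalues=P[keep],
        flipped=flipped[keep],
        ambiguous=ambiguous[keep],
        cohorts=list(cohorts),
        counts=counts,
    )
    if not np.all(np.isfinite(panel.Z)):
        raise ValueError("harmonized z-statistics contain non-finite values")
    return panel


def _chrom_sort_key(chrom: pd.Series) -> np.ndarray:
    """Numeric-aware chromosome order: 1..22 numerically, then X, Y, MT, others."""
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}

    def one(c):
        c = str(c).removeprefix("chr")
        if c.isdigit():
            return int(c)
        return special.get(c.upper(), 99)

    return np.fromiter((one(c) for c in chrom), dtype=np.int64, count=len(chrom))


def save_panel(panel: HarmonizedPanel, path) -> None:
    """Persist a panel as a parquet table plus a JSON manifest of counts."""
    path = Path(path)
    panel.to_frame().to_parquet(path, index=False)
    manifest = {
        "cohorts": panel.cohorts,
        "N": panel.N.tolist(),
        "counts": panel.counts,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=1))


def load_panel(path) -> HarmonizedPanel:
    path = Path(path)
    df = pd.read_parquet(path)
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cohorts = manifest["cohorts"]
    Z = df[[f"z_{c}" for c in cohorts]].to_numpy()
    P = df[[f"p_{c}" for c in cohorts]].to_numpy()
    variants = df[["key", "chrom", "pos", "a1", "a2", "rsid"]]
    return HarmonizedPanel(
        variants=variants,
        Z=Z,
        N=np.asarray(manifest["N"], dtype=float),
        pvalues=P,
        flipped=np.zeros(Z.shape, dtype=bool),
        ambiguous=df["ambiguous"].to_numpy(dtype=bool),
        cohorts=cohorts,
        counts=manifest.get("counts", {}),
    )
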