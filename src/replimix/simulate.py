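"""Synthetic GWAS summary data with the structure the replication model assumes.

Each of J variants carries, per cohort, a latent association indicator in
{-1, 0, +1}.  Indicators are drawn independently across cohorts and variants:
cohort k is non-null with its own causal proportion, and the realized causal
set of each cohort is split exactly in half between positive and negative
effects (odd counts differ by one).  A variant is *truly replicated* when it
is non-null with the same sign in every cohort; with balanced independent
signs this happens for a fraction ``prod(pi_k) * 2 / 2^K`` of variants in
expectation.

z-statistics are drawn as ``z_jk ~ Normal(H_jk * mu, sd^2)``, independent
across variants and cohorts, i.e. no linkage disequilibrium and no
cross-cohort correlation of noise.

The module also writes raw per-cohort summary-statistic tables with deliberate
allele flips and cohort-private variants, as fixtures for the harmonization
stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimulationConfig",
    "TruthMatrix",
    "SumstatsFixture",
    "generate_truth",
    "generate_z",
    "generate_sumstats_fixture",
    "write_sumstats",
    "save_zmatrix",
    "load_zmatrix",
]

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation cell.

    ``effect_mean`` is the mean magnitude of causal z-statistics (the x-axis
    of the power/FDR curves); ``causal_proportions`` gives each cohort's
    probability that a variant is non-null there.
    """

    J: int
    K: int
    causal_proportions: tuple
    effect_mean: float
    effect_sd: float = 1.0
    n_reps: int = 1
    seed: int = 0
    nominal_fdr: float = 0.1

    def __post_init__(self):
        object.__setattr__(
            self, "causal_proportions", tuple(float(p) for p in np.atleast_1d(self.causal_proportions))
        )
        if self.J < 1:
            raise ValueError("J must be positive")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if len(self.causal_proportions) != self.K:
            raise ValueError("need one causal proportion per cohort")
        for p in self.causal_proportions:
            if not np.isfinite(p) or not 0.0 <= p < 1.0:
                raise ValueError(f"causal proportions must lie in [0, 1), got {p}")
        if not np.isfinite(self.effect_mean) or self.effect_mean <= 0:
            raise ValueError("effect_mean must be positive")
        if not np.isfinite(self.effect_sd) or self.effect_sd <= 0:
            raise ValueError("effect_sd must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.nominal_fdr < 1.0:
            raise ValueError("nominal_fdr must lie in (0, 1)")

    def expected_causal_counts(self) -> tuple:
        """Expected number of causal variants per cohort, pi_k * J."""
        return tuple(p * self.J for p in self.causal_proportions)

    def expected_all_causal_fraction(self) -> float:
        """Expected fraction of variants causal in every cohort, prod(pi_k)."""
        return float(np.prod(self.causal_proportions))

    def expected_replicated_fraction(self) -> float:
        """Expected fraction truly replicated: all causal with one shared sign.

        With balanced signs independent across cohorts, 2 of the 2^K sign
        patterns agree, so the fraction is prod(pi_k) * 2 / 2^K.
        """
        return self.expected_all_causal_fraction() * 2.0 / 2.0**self.K


@dataclass(frozen=True)
class TruthMatrix:
    """Ground-truth configuration matrix H (J x K, entries in {-1, 0, +1})."""

    H: np.ndarray
    replicated: np.ndarray = field(init=False)

    def __post_init__(self):
        H = np.asarray(self.H, dtype=np.int8)
        if H.ndim != 2:
            raise ValueError("H must be a J x K matrix")
        if not np.all(np.isin(H, (-1, 0, 1))):
            raise ValueError("H entries must be in {-1, 0, +1}")
        object.__setattr__(self, "H", H)
        replicated = np.all(H == 1, axis=1) | np.all(H == -1, axis=1)
        object.__setattr__(self, "replicated", replicated)

    @property
    def J(self) -> int:
        return self.H.shape[0]

    @property
    def K(self) -> int:
        return self.H.shape[1]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_truth(config: SimulationConfig, seed=None) -> TruthMatrix:
    """Draw the latent configuration matrix for one replicate.

    Causal indicators are independent across cohorts and variants; within
    each cohort the realized causal set is split exactly in half between +1
    and -1 (an odd count leaves the two differing by one, the extra sign
    chosen at random).  Deterministic given the seed.
    """
    rng = _rng(config.seed if seed is None else seed)
    H = np.zeros((config.J, config.K), dtype=np.int8)
    for k, pi in enumerate(config.causal_proportions):
        if pi == 0.0:
            continue
        causal = np.flatnonzero(rng.random(config.J) < pi)
        rng.shuffle(causal)
        n = causal.size
        n_pos = n // 2
        if n % 2 == 1 and rng.integers(2) == 1:
            n_pos += 1
        H[causal[:n_pos], k] = 1
        H[causal[n_pos:], k] = -1
    return TruthMatrix(H=H)


def generate_z(
    truth: TruthMatrix, effect_mean: float, effect_sd: float = 1.0, seed=None
) -> np.ndarray:
    """Draw z_jk ~ Normal(H_jk * effect_mean, effect_sd^2), independently."""
    if not np.isfinite(effect_sd) or effect_sd <= 0:
        raise ValueError("effect_sd must be positive")
    if not np.isfinite(effect_mean):
        raise ValueError("effect_mean must be finite")
    rng = _rng(seed)
    return rng.normal(truth.H * float(effect_mean), float(effect_sd))


# ---------------------------------------------------------------------------
# raw summary-statistic fixtures for the harmonization stage

FIXTURE_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N"]


@dataclass(frozen=True)
class SumstatsFixture:
    """Per-cohort summary tables plus the generator's internal truth.

    ``truth`` records, per backbone variant, the signed effect in the
    orientation of cohort 0 and which cohorts carry the variant; correct
    harmonization must recover these signs exactly.
    """

    tables: list
    truth: pd.DataFrame

    def __iter__(self):
        return iter(self.tables)

    def __len__(self):
        return len(self.tables)


def generate_sumstats_fixture(
    n_variants: int,
    cohorts: int = 2,
    flip_fraction: float = 0.0,
    drop_fraction: float = 0.0,
    seed: int = 0,
) -> SumstatsFixture:
    """Build cohort summary tables sharing a variant backbone.

    A ``flip_fraction`` of each non-reference cohort's shared variants has
    its effect/other alleles swapped and its effect size negated, so that
    allele-aware harmonization recovers identical signed effects.  A
    ``drop_fraction`` of backbone variants is private to a single random
    cohort.  Allele pairs are drawn uniformly from distinct nucleotides and
    so include strand-ambiguous A/T and C/G pairs.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be positive")
    if cohorts < 2:
        raise ValueError("need at least two cohorts")
    for name, frac in (("flip_fraction", flip_fraction), ("drop_fraction", drop_fraction)):
        if not np.isfinite(frac) or not 0.0 <= frac < 1.0:
            raise ValueError(f"{name} must lie in [0, 1), got {frac}")
    rng = _rng(seed)

    chrom = rng.integers(1, 23, size=n_variants)
    bp = rng.choice(np.arange(1, 50 * n_variants + 1), size=n_variants, replace=False)
    a_idx = rng.integers(0, 4, size=n_variants)
    shift = rng.integers(1, 4, size=n_variants)
    a1 = _NUCLEOTIDES[a_idx]
    a2 = _NUCLEOTIDES[(a_idx + shift) % 4]
    beta = rng.normal(0.0, 0.25, size=n_variants)

    private = rng.random(n_variants) < drop_fraction
    owner = rng.integers(0, cohorts, size=n_variants)

    key = [
        f"{c}:{p}:{min(x, y)}:{max(x, y)}"
        for c, p, x, y in zip(chrom, bp, a1, a2)
    ]
    truth = pd.DataFrame(
        {
            "key": key,
            "SNP": [f"rs{i + 1}" for i in range(n_variants)],
            "beta": beta,
            "shared": ~private,
            "owner": np.where(private, owner, -1),
        }
    )

    tables = []
    for k in range(cohorts):
        keep = ~private | (owner == k)
        se = rng.uniform(0.08, 0.12, size=n_variants)
        tab = pd.DataFrame(
            {
                "SNP": truth["SNP"],
                "CHR": chrom,
                "BP": bp,
                "A1": a1,
                "A2": a2,
                "BETA": beta,
                "SE": se,
                "N": 50_000 + 1_000 * k,
            }
        )[keep].reset_index(drop=True)
        if k > 0 and flip_fraction > 0.0:
            flip = rng.random(len(tab)) < flip_fraction
            tab.loc[flip, ["A1", "A2"]] = tab.loc[flip, ["A2", "A1"]].to_numpy()
            tab.loc[flip, "BETA"] = -tab.loc[flip, "BETA"]
        tab["P"] = np.clip(2.0 * norm.sf(np.abs(tab["BETA"] / tab["SE"])), 1e-300, 1.0)
        tables.append(tab[FIXTURE_COLUMNS])
    return SumstatsFixture(tables=tables, truth=truth)


def write_sumstats(table: pd.DataFrame, path) -> None:
    """Write a summary-statistic table as tab-delimited text with header."""
    table.to_csv(path, sep="\t", index=False)


def save_zmatrix(
    Z: np.ndarray, path, config: SimulationConfig | None = None, seed: int | None = None,
    truth: TruthMatrix | None = None,
) -> None:
    """Persist a z-matrix (and optional truth) as parquet + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(Z, columns=[f"z{k}" for k in range(Z.shape[1])])
    if truth is not None:
        for k in range(truth.K):
            df[f"h{k}"] = truth.H[:, k]
    df.to_parquet(path, index=False)
    meta = {"seed": seed, "config": asdict(config) if config is not None else None}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_zmatrix(path):
    """Load a persisted z-matrix; returns (Z, truth-or-None, metadata)."""
    path = Path(path)
    df = pd.read_parquet(path)
    zcols = [c for c in df.columns if c.startswith("z")]
    hcols = [c for c in df.columns if c.startswith("h")]
    Z = df[zcols].to_numpy()
    truth = TruthMatrix(H=df[hcols].to_numpy()) if hcols else None
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Z, truth, meta
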