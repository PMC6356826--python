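"""Synthetic data with known inheritance-mode ground truth.

The generator emulates the study design this package targets: two highly
inbred parental lines (F and L) crossed reciprocally, with RNA-seq count
data for a handful of biological replicates per group (defaults: 2 F, 2 L,
4 FL, 4 LF).  Each gene is assigned a true transgenerational inheritance
mode and group expectations are set accordingly:

========================  ==================================================
mode                      expected normalized means
========================  ==================================================
null                      mu_F = mu_L = mu_Cross = m
additive                  mu_F = m 2^(+/- d/2), mu_L = m 2^(-/+ d/2),
                          mu_Cross = (mu_F + mu_L) / 2
dominance_F               mu_Cross = mu_F
dominance_L               mu_Cross = mu_L
over_dominance            mu_Cross = max(mu_F, mu_L) 2^D
under_dominance           mu_Cross = min(mu_F, mu_L) 2^(-D)
========================  ==================================================

where ``d`` is the parental log2 fold change and ``D`` the margin beyond
the extreme parent.  Counts are negative-binomial with variance
``mu + alpha mu^2`` (the same parameterization as the testing engine),
scaled by per-sample library size factors.  Reciprocal crosses share
mu_Cross by default; ``reciprocal_log2fc`` injects an FL vs LF difference.

Allele-specific expression is simulated at the gene level: for ASE genes
the F-allele read count in each cross sample is binomial around a skewed
allelic ratio; non-ASE genes sit at 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import AseTable, CountMatrix, PhenotypeTable, ValidationError

MODES = (
    "null",
    "additive",
    "dominance_F",
    "dominance_L",
    "over_dominance",
    "under_dominance",
)

#: per-group replicate numbers of the emulated sequencing design
DEFAULT_N_PER_GROUP = {"F": 2, "L": 2, "FL": 4, "LF": 4}

#: a realistic transcriptome-wide mix: most genes do not differ between the
#: lines at all, and among divergent genes additivity dominates.
DEFAULT_MODE_PROPORTIONS = {
    "null": 0.70,
    "additive": 0.10,
    "dominance_F": 0.08,
    "dominance_L": 0.08,
    "over_dominance": 0.02,
    "under_dominance": 0.02,
}


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the count-matrix generator.

    parental_log2fc
        Effect size ``d``: log2(mu_F / mu_L) magnitude for parentally
        divergent genes (direction randomized per gene).
    overdominance_log2fc
        Margin ``D`` beyond the extreme parent for over/under-dominance.
    dispersion / dispersion_log_sd
        NB dispersion alpha; when ``dispersion_log_sd > 0`` per-gene alphas
        are log-normal around ``dispersion``.
    baseline_log_mean, baseline_log_sd
        Natural-log-normal parameters of per-gene baseline means.
    size_factor_range
        Per-sample library size factors drawn uniformly from this interval.
    ase_fraction / ase_allelic_ratio
        Fraction of genes with allelic imbalance and the F-allele fraction
        for imbalanced genes (side randomized per gene).
    """

    n_genes: int = 2000
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    mode_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_PROPORTIONS)
    )
    parental_log2fc: float = 4.0
    overdominance_log2fc: float = 2.0
    dispersion: float = 0.1
    dispersion_log_sd: float = 0.0
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.5
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    reciprocal_log2fc: float = 0.0
    ase_fraction: float = 0.15
    ase_allelic_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        for g, n in self.n_per_group.items():
            if n <= 0:
                raise ConfigError(f"n_per_group[{g}] must be positive")
        unknown = set(self.mode_proportions) - set(MODES)
        if unknown:
            raise ConfigError(f"unknown modes in proportions: {unknown}")
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mode proportions sum to {total}, not 1")
        for name in ("parental_log2fc", "overdominance_log2fc"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ConfigError("size_factor_range must be 0 < lo <= hi")
        if not 0 <= self.ase_fraction <= 1:
            raise ConfigError("ase_fraction must be in [0, 1]")
        if not 0 < self.ase_allelic_ratio < 1:
            raise ConfigError("ase_allelic_ratio must be in (0, 1)")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, alpha) with variance mean + alpha mean^2; Poisson at alpha ~ 0."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    rest = ~tiny
    if rest.any():
        r = 1.0 / alpha[rest]
        p = r / (r + mean[rest])
        out[rest] = rng.negative_binomial(r, p)
    return out


def _assign_modes(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    modes = [m for m in MODES if cfg.mode_proportions.get(m, 0.0) > 0]
    probs = np.array([cfg.mode_proportions[m] for m in modes])
    probs = probs / probs.sum()
    return rng.choice(modes, size=cfg.n_genes, p=probs)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a count matrix plus a per-gene ground-truth table.

    Returns the validated :class:`CountMatrix` and a ``SimTruth`` DataFrame
    indexed by gene id with columns ``true_mode``, ``sub_mode``, ``mu_F``,
    ``mu_L``, ``mu_Cross``, ``is_ase``, ``allelic_ratio``.  Deterministic
    for a fixed config (including its seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(G)]

    mode = _assign_modes(rng, cfg)
    m = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, G))
    sign = rng.choice([-1.0, 1.0], size=G)
    half = cfg.parental_log2fc / 2.0

    divergent = mode != "null"
    mu_F = np.where(divergent, m * 2.0 ** (sign * half), m)
    mu_L = np.where(divergent, m * 2.0 ** (-sign * half), m)

    hi = np.maximum(mu_F, mu_L)
    lo = np.minimum(mu_F, mu_L)
    mpv = (mu_F + mu_L) / 2.0
    mu_X = np.select(
        [
            mode == "null",
            mode == "additive",
            mode == "dominance_F",
            mode == "dominance_L",
            mode == "over_dominance",
            mode == "under_dominance",
        ],
        [m, mpv, mu_F, mu_L, hi * 2.0 ** cfg.overdominance_log2fc,
         lo * 2.0 ** (-cfg.overdominance_log2fc)],
    )

    # enhancing iff the resembled parent is the higher-expressed parent
    sub = np.full(G, "none", dtype=object)
    dom_f = mode == "dominance_F"
    dom_l = mode == "dominance_L"
    sub[dom_f] = np.where(mu_F[dom_f] > mu_L[dom_f], "enhancing", "suppressing")
    sub[dom_l] = np.where(mu_L[dom_l] > mu_F[dom_l], "enhancing", "suppressing")

    # per-gene dispersion
    if cfg.dispersion_log_sd > 0:
        alpha = np.exp(
            rng.normal(math.log(cfg.dispersion), cfg.dispersion_log_sd, G)
        )
    else:
        alpha = np.full(G, cfg.dispersion)

    # sample layout, size factors, group means
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    cols: list[np.ndarray] = []
    rhalf = cfg.reciprocal_log2fc / 2.0
    group_mu = {
        "F": mu_F,
        "L": mu_L,
        "FL": mu_X * 2.0 ** rhalf,
        "LF": mu_X * 2.0 ** (-rhalf),
    }
    lo_sf, hi_sf = cfg.size_factor_range
    for g in ("F", "L", "FL", "LF"):
        for k in range(cfg.n_per_group.get(g, 0)):
            sid = f"{g}_{k + 1}"
            sample_ids.append(sid)
            groups[sid] = g
            s_j = rng.uniform(lo_sf, hi_sf)
            cols.append(_nb_draw(rng, s_j * group_mu[g], alpha))

    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )

    is_ase = rng.random(G) < cfg.ase_fraction
    side = rng.choice([True, False], size=G)  # True -> F allele preferred
    ratio = np.where(
        is_ase,
        np.where(side, cfg.ase_allelic_ratio, 1.0 - cfg.ase_allelic_ratio),
        0.5,
    )

    truth = pd.DataFrame(
        {
            "true_mode": mode,
            "sub_mode": sub,
            "mu_F": mu_F,
            "mu_L": mu_L,
            "mu_Cross": mu_X,
            "is_ase": is_ase,
            "allelic_ratio": ratio,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return CountMatrix(counts, groups), truth


def simulate_ase(
    truth: pd.DataFrame,
    cross_samples: list[str],
    depth_mean: float = 50.0,
    seed: int = 0,
) -> tuple[AseTable, pd.DataFrame]:
    """Gene-level allelic counts for cross samples plus the derived ASE table.

    For each gene and cross sample the allele-informative read total is
    Poisson(``depth_mean``) and the F-allele count binomial at the gene's
    true allelic ratio.  The ASE table lists the imbalanced genes with the
    preferred allele taken from the side of the true ratio.
    """
    rng = np.random.default_rng(seed)
    genes = truth.index
    G, S = len(genes), len(cross_samples)
    totals = rng.poisson(depth_mean, size=(G, S))
    ratio = truth["allelic_ratio"].to_numpy()[:, None]
    f_counts = rng.binomial(totals, np.broadcast_to(ratio, (G, S)))

    counts = pd.DataFrame(
        {
            "gene_id": np.repeat(genes, S),
            "sample_id": np.tile(cross_samples, G),
            "total": totals.ravel(),
            "f_allele": f_counts.ravel(),
        }
    )

    ase_genes = truth.index[truth["is_ase"]]
    pref = np.where(truth.loc[ase_genes, "allelic_ratio"] > 0.5, "F", "L")
    table = pd.DataFrame(
        {
            "gene_id": ase_genes,
            "preferred_allele": pref,
            "conflicting": False,
        }
    ).reset_index(drop=True)
    return AseTable(table), counts


#: embryo-weight group means (g) mirroring the emulated study's phenotype
DEFAULT_EMBRYO_MEANS = {"F": 3.53, "L": 3.75, "FL": 4.03, "LF": 4.03}
DEFAULT_EGG_MEANS = {"F": 39.7, "L": 33.1, "FL": 37.1, "LF": 37.1}
DEFAULT_PHENOTYPE_N = {"F": 14, "L": 16, "FL": 14, "LF": 4}


def simulate_phenotypes(
    n_per_group: Mapping[str, int] | None = None,
    embryo_means: Mapping[str, float] | None = None,
    egg_means: Mapping[str, float] | None = None,
    embryo_sd: float = 0.45,
    egg_sd: float = 2.5,
    seed: int = 0,
) -> PhenotypeTable:
    """Normal per-embryo egg and embryo weights around group means."""
    if embryo_sd < 0 or egg_sd < 0:
        raise ConfigError("standard deviations must be non-negative")
    n_per_group = dict(n_per_group or DEFAULT_PHENOTYPE_N)
    embryo_means = dict(embryo_means or DEFAULT_EMBRYO_MEANS)
    egg_means = dict(egg_means or DEFAULT_EGG_MEANS)
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in n_per_group.items():
        eggs = rng.normal(egg_means[g], egg_sd, n)
        embryos = rng.normal(embryo_means[g], embryo_sd, n)
        for k in range(n):
            rows.append(
                {
                    "sample_id": f"{g}_ph{k + 1}",
                    "group": g,
                    "egg_weight": eggs[k],
                    "embryo_weight": embryos[k],
                }
            )
    return PhenotypeTable(pd.DataFrame(rows))
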