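"""Negative-binomial two-group differential expression testing.

A self-contained engine: median-of-ratios size factors, method-of-moments
dispersion with optional moderation toward the transcriptome-wide mean,
a delta-method Wald test on the log2 fold change, Benjamini-Hochberg
adjustment, and the decision rule ``q < alpha AND |log2FC| >= lfc_min``.

The NB parameterization throughout is ``Var = mu + alpha * mu^2``.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CountMatrix, ValidationError, group_samples

DISPERSION_FLOOR = 1e-8

#: contrasts whose DE genes enter the compiled per-tissue gene list
CONTRASTS_FOR_GENE_LIST = ("F_vs_L", "F_vs_Cross", "L_vs_Cross", "MPV_vs_Cross")

#: all pairwise comparisons the pipeline runs
ALL_CONTRASTS = (
    ("F", "L"),
    ("F", "Cross"),
    ("L", "Cross"),
    ("FL", "LF"),
    ("MPV", "Cross"),
)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Reference genes are those with strictly positive counts in every
    sample; the factor for sample j is the median over reference genes of
    count[i, j] / geometric-mean_i.  Factors are not rescaled afterwards.
    """
    vals = counts.to_numpy(dtype=float)
    ref = (vals > 0).all(axis=1)
    if not ref.any():
        raise ValidationError(
            "no gene has positive counts in all samples; "
            "cannot form the median-of-ratios reference"
        )
    logs = np.log(vals[ref])
    geo = np.exp(logs.mean(axis=1))
    ratios = vals[ref] / geo[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if (factors <= 0).any():
        raise ValidationError("size factors must be positive")
    return counts / factors.reindex(counts.columns)


def estimate_dispersion(
    normalized: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-gene method-of-moments NB dispersion from within-group moments.

    For each group g with n_g >= 2 samples, ``alpha_g = max((v - m)/m^2, 0)``
    from the within-group sample mean m and variance v; the gene estimate is
    the (n_g - 1)-weighted average over groups, floored at 1e-8.  Genes with
    zero mean in every group are flagged untestable.
    """
    usable = {g: list(s) for g, s in groups.items() if len(s) >= 2}
    if not usable:
        raise ValidationError("dispersion needs at least one group with >= 2 samples")
    num = np.zeros(len(normalized))
    den = 0.0
    all_zero = np.ones(len(normalized), dtype=bool)
    for g, samples in usable.items():
        x = normalized[samples].to_numpy(dtype=float)
        n = x.shape[1]
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.square(np.where(m > 0, m, 1.0)), 0.0)
        a = np.maximum(a, 0.0)
        num += (n - 1) * a
        den += n - 1
        all_zero &= m == 0
    alpha = np.maximum(num / den, DISPERSION_FLOOR)
    return pd.DataFrame(
        {"alpha": alpha, "untestable": all_zero}, index=normalized.index
    )


def moderate_dispersion(
    disp: pd.DataFrame, residual_df: float, prior_df: float = 10.0
) -> pd.DataFrame:
    """Shrink per-gene dispersions toward the across-gene mean.

    A weighted average of the gene estimate (weight = residual degrees of
    freedom) and the mean dispersion of testable genes (weight =
    ``prior_df``).  Stabilizes the Wald test's type-I error at the small
    replicate numbers this design uses.
    """
    testable = ~disp["untestable"]
    trend = float(disp.loc[testable, "alpha"].mean()) if testable.any() else DISPERSION_FLOOR
    alpha = (residual_df * disp["alpha"] + prior_df * trend) / (residual_df + prior_df)
    out = disp.copy()
    out["alpha"] = np.maximum(alpha, DISPERSION_FLOOR)
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def wald_contrast(
    normalized: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    a: str,
    b: str,
    alpha_vec: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Wald test of group b vs group a on normalized counts.

    ``log2fc = log2((mean_b + c) / (mean_a + c))`` with pseudocount c; the
    standard error is the delta-method variance of the log of an NB mean,
    ``se = sqrt(w_a + w_b) / ln 2`` with ``w_g = (1/max(mean_g, c) + alpha)
    / n_g``; p is the two-sided standard-normal tail of ``log2fc / se``.
    Genes with zero mean in both groups are untestable (p = 1).
    """
    sa, sb = list(groups[a]), list(groups[b])
    if not sa or not sb:
        raise ValidationError(f"contrast {a} vs {b}: empty group")
    c = pseudocount
    xa = normalized[sa].to_numpy(dtype=float)
    xb = normalized[sb].to_numpy(dtype=float)
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    al = alpha_vec.reindex(normalized.index).to_numpy(dtype=float)
    lfc = np.log2((mb + c) / (ma + c))
    w = (1.0 / np.maximum(ma, c) + al) / len(sa) + (
        1.0 / np.maximum(mb, c) + al
    ) / len(sb)
    se = np.sqrt(w) / math.log(2.0)
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    untestable = (ma == 0) & (mb == 0)
    p = np.where(untestable, 1.0, p)
    return pd.DataFrame(
        {
            "group_a": a,
            "group_b": b,
            "mean_a": ma,
            "mean_b": mb,
            "log2fc": lfc,
            "se": se,
            "p": p,
            "untestable": untestable,
        },
        index=normalized.index,
    )


def finish_contrast(
    result: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Attach BH-adjusted q and the DE decision to a Wald result table.

    Untestable genes are excluded from the number of BH hypotheses and get
    q = 1, is_de = False.
    """
    out = result.copy()
    p = out["p"].to_numpy(dtype=float).copy()
    p[out["untestable"].to_numpy(bool)] = np.nan
    q = bh_adjust(p)
    q = np.where(np.isnan(q), 1.0, q)
    out["q"] = q
    out["is_de"] = (
        (out["q"] < alpha)
        & (out["log2fc"].abs() >= lfc_min)
        & ~out["untestable"]
    )
    return out


def run_contrast(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudocount: float = 0.5,
    moderate: bool = True,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Full two-group DE analysis on a raw count matrix.

    Size factors come from the non-MPV samples (MPV pseudo-samples, which
    are already on the normalized scale, get factor 1).  ``Cross`` pools
    the FL and LF samples.
    """
    samples_a = cm.samples_in(group_a)
    samples_b = cm.samples_in(group_b)
    if len(samples_a) < 1 or len(samples_b) < 1:
        raise ValidationError(f"contrast {group_a} vs {group_b}: empty group")
    real = [s for s in cm.sample_ids if cm.groups[s] != "MPV"]
    factors = size_factors(cm.counts[real]) if real else pd.Series(dtype=float)
    mpv = [s for s in cm.sample_ids if cm.groups[s] == "MPV"]
    factors = pd.concat([factors, pd.Series(1.0, index=mpv)])
    norm = normalize(cm.counts, factors)
    groups = {group_a: samples_a, group_b: samples_b}
    disp = estimate_dispersion(norm, {g: s for g, s in groups.items() if len(s) >= 2})
    if moderate:
        residual_df = sum(len(s) - 1 for s in groups.values() if len(s) >= 2)
        disp = moderate_dispersion(disp, residual_df, prior_df)
    res = wald_contrast(norm, groups, group_a, group_b, disp["alpha"], pseudocount)
    return finish_contrast(res, alpha=alpha, lfc_min=lfc_min)
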