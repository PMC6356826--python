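"""Phenotype-level heterosis statistics.

Embryonic efficiency (embryo weight as a percentage of egg weight), a
Shapiro-Wilk normality screen, one-way ANOVA across groups, and
Tukey-Kramer all-pairs comparisons with a compact letter display (groups
sharing no letter differ at the chosen level).  The phenotype mid-parent
group, built by pairing F and L embryos, enters the comparisons as a
group of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data_model import PhenotypeTable, ValidationError
from .mpv import build_mpv_phenotype


def embryonic_efficiency(phenotypes: PhenotypeTable | pd.DataFrame) -> pd.Series:
    """Per-sample efficiency: 100 x embryo_weight / egg_weight (percent)."""
    t = phenotypes.table if isinstance(phenotypes, PhenotypeTable) else phenotypes
    if (t["embryo_weight"] >= t["egg_weight"]).any():
        raise ValidationError("embryo weight must be below egg weight")
    eff = 100.0 * t["embryo_weight"] / t["egg_weight"]
    eff.index = t["sample_id"]
    return eff.rename("efficiency")


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 <= n <= 5000 required)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk undefined for constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def letter_display(
    group_order: Sequence[str], different: set[frozenset[str]]
) -> dict[str, str]:
    """Compact letter display from pairwise 'significantly different' pairs.

    Groups are taken in the given order (conventionally sorted by mean);
    maximal runs of mutually non-different groups share a letter, so two
    groups that share no letter are significantly different.
    """
    order = list(group_order)
    n = len(order)

    def ok(i: int, j: int) -> bool:
        return frozenset((order[i], order[j])) not in different

    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and all(ok(a, j + 1) for a in range(i, j + 1)):
            j += 1
        runs.append((i, j))
        i += 1
    # keep only maximal runs
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    maximal = sorted(set(maximal))
    letters = {g: "" for g in order}
    for idx, (a, b) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for k in range(a, b + 1):
            letters[order[k]] += ch
    return letters


@dataclass
class TukeyResult:
    anova_f: float
    anova_p: float
    comparisons: pd.DataFrame  # group_a, group_b, mean_diff, p, significant
    letters: dict[str, str]
    excluded_groups: list[str] = field(default_factory=list)


def group_anova_tukey(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> TukeyResult:
    """One-way ANOVA plus Tukey-Kramer all-pairs comparisons.

    Groups with fewer than 2 observations are excluded (recorded on the
    result).  The Tukey-Kramer studentized-range procedure honors unequal
    group sizes; the letter display is derived from the pairwise
    reject/accept decisions.
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)})
    sizes = df.groupby("group").size()
    excluded = sorted(sizes.index[sizes < 2])
    df = df[~df["group"].isin(excluded)]
    kept = sorted(df["group"].unique())
    if len(kept) < 2:
        raise ValidationError("need at least 2 groups with >= 2 samples")

    arrays = [df.loc[df["group"] == g, "value"].to_numpy() for g in kept]
    f_stat, f_p = stats.f_oneway(*arrays)

    tk = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy(), alpha=alpha)
    ii, jj = np.triu_indices(len(tk.groupsunique), 1)
    comp = pd.DataFrame(
        {
            "group_a": [str(tk.groupsunique[i]) for i in ii],
            "group_b": [str(tk.groupsunique[j]) for j in jj],
            "mean_diff": tk.meandiffs,
            "p": tk.pvalues,
            "significant": tk.reject,
        }
    )
    different = {
        frozenset((r.group_a, r.group_b))
        for r in comp.itertuples()
        if r.significant
    }
    means = df.groupby("group")["value"].mean().sort_values(ascending=False)
    letters = letter_display(list(means.index), different)
    return TukeyResult(
        anova_f=float(f_stat),
        anova_p=float(f_p),
        comparisons=comp,
        letters=letters,
        excluded_groups=excluded,
    )


@dataclass
class PhenotypeSummary:
    group_stats: pd.DataFrame  # group x (variable, n, mean, sd)
    normality: pd.DataFrame  # variable, W, p
    results: dict[str, TukeyResult]  # per variable


def summarize_phenotypes(
    phenotypes: PhenotypeTable,
    mpv_seed: int = 0,
    include_mpv: bool = True,
    pool_crosses: bool = True,
    alpha: float = 0.05,
) -> PhenotypeSummary:
    """Group summaries, normality screen, and ANOVA/Tukey for all variables.

    Reciprocal crosses are pooled into a ``Cross`` group by default; the
    mid-parent group is appended from randomly paired parental embryos.
    """
    t = phenotypes.table.copy()
    if include_mpv:
        mpv_rows, _ = build_mpv_phenotype(phenotypes, seed=mpv_seed)
        t = pd.concat([t, mpv_rows], ignore_index=True)
    if pool_crosses:
        t["group"] = t["group"].replace({"FL": "Cross", "LF": "Cross"})
    t["efficiency"] = 100.0 * t["embryo_weight"] / t["egg_weight"]

    variables = ("egg_weight", "embryo_weight", "efficiency")
    stats_rows = []
    for g, sub in t.groupby("group"):
        for var in variables:
            stats_rows.append(
                {
                    "group": g,
                    "variable": var,
                    "n": len(sub),
                    "mean": float(sub[var].mean()),
                    "sd": float(sub[var].std(ddof=1)),
                }
            )
    normality_rows = []
    for var in variables:
        w, p = shapiro_wilk(t[var])
        normality_rows.append({"variable": var, "W": w, "p": p})
    results = {
        var: group_anova_tukey(t[var], t["group"], alpha=alpha) for var in variables
    }
    return PhenotypeSummary(
        group_stats=pd.DataFrame(stats_rows),
        normality=pd.DataFrame(normality_rows),
        results=results,
    )
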