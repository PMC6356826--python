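"""Overlap between inheritance-mode categories and allele-specific expression.

Builds the lower-triangular cross-tabulation of DE-pattern categories
(additive A, over-dominance OD, Fayoumi-dominance D_F, Leghorn-dominance
D_L — all restricted to the compiled DE gene list) against gene-level ASE
categories split by preferred parental allele (ASE_F, ASE_L), and tests
DE x ASE independence with a Pearson chi-squared test on the 2x2 table
over a gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AseTable, ValidationError

CATEGORIES = ("A", "OD", "D_F", "D_L", "ASE_F", "ASE_L")

_MODE_TO_CATEGORY = {
    "additive": "A",
    "over_dominance": "OD",
    "dominance_F": "D_F",
    "dominance_L": "D_L",
}


@dataclass
class OverlapMatrix:
    """Lower-triangular category overlap counts plus the underlying sets."""

    table: pd.DataFrame
    sets: dict[str, set[str]]

    def cell(self, a: str, b: str) -> int:
        i, j = CATEGORIES.index(a), CATEGORIES.index(b)
        if i < j:
            i, j = j, i
        return int(self.table.iloc[i, j])


def category_sets(
    calls: pd.DataFrame, ase: AseTable, de_gene_list: Iterable[str]
) -> dict[str, set[str]]:
    """Gene sets per category; DE-pattern categories restricted to the DE list."""
    de = set(de_gene_list)
    unknown = de - set(calls.index)
    if unknown:
        raise ValidationError(
            f"DE-list genes missing from calls: {sorted(unknown)[:5]}"
        )
    sets: dict[str, set[str]] = {}
    for mode, cat in _MODE_TO_CATEGORY.items():
        sets[cat] = set(calls.index[calls["mode"] == mode]) & de
    sets["ASE_F"] = ase.preferred("F")
    sets["ASE_L"] = ase.preferred("L")
    return sets


def overlap_from_sets(sets: Mapping[str, Iterable[str]]) -> OverlapMatrix:
    """Lower-triangle pairwise intersection counts; diagonal = set sizes."""
    s = {c: set(sets.get(c, ())) for c in CATEGORIES}
    n = len(CATEGORIES)
    mat = np.full((n, n), np.nan)
    for i, a in enumerate(CATEGORIES):
        for j, b in enumerate(CATEGORIES[: i + 1]):
            mat[i, j] = len(s[a] & s[b]) if a != b else len(s[a])
    table = pd.DataFrame(mat, index=CATEGORIES, columns=CATEGORIES)
    return OverlapMatrix(table, s)


def build_overlap(
    calls: pd.DataFrame, ase: AseTable, de_gene_list: Iterable[str]
) -> OverlapMatrix:
    """Cross-tabulate inheritance calls against ASE categories.

    ASE genes with conflicting preferred alleles are excluded by
    construction (:meth:`AseTable.preferred` skips them).
    """
    return overlap_from_sets(category_sets(calls, ase, de_gene_list))


def ase_de_fraction(overlap: OverlapMatrix, de_gene_list: Iterable[str]) -> float:
    """Fraction of the compiled DE gene list that is also (usable) ASE."""
    de = set(de_gene_list)
    if not de:
        raise ValidationError("DE gene list is empty; fraction undefined")
    ase = overlap.sets["ASE_F"] | overlap.sets["ASE_L"]
    return len(de & ase) / len(de)


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p: float
    significant: bool
    table: np.ndarray
    expected: np.ndarray
    warning: str | None = None


def chi2_independence(
    de_set: Iterable[str],
    ase_set: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.05,
    continuity_correction: bool = False,
) -> Chi2Result:
    """Pearson chi-squared test of DE x ASE independence over a gene universe.

    The 2x2 table cross-classifies every universe gene by DE membership and
    ASE membership.  No continuity correction by default.  A warning is
    attached (not raised) when any expected cell is below 1.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty gene universe")
    de = set(de_set) & uni
    ase = set(ase_set) & uni
    a = len(de & ase)
    b = len(de - ase)
    c = len(ase - de)
    d = len(uni) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chi2, p, dof, expected = stats.chi2_contingency(
            table, correction=continuity_correction
        )
    note = None
    if (expected < 1).any():
        note = "expected cell count below 1; chi-squared approximation unreliable"
    return Chi2Result(
        statistic=float(chi2),
        df=int(dof),
        p=float(p),
        significant=bool(p < alpha),
        table=table,
        expected=expected,
        warning=note,
    )
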