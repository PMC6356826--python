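"""Per-gene transgenerational inheritance-mode classification.

A gene's mode is decided from four two-group contrasts — F vs L,
F vs Cross, L vs Cross, and MPV vs Cross — plus the group means:

1. Any contrast untestable -> ``untestable``.
2. Cross not DE from the mid-parent value -> ``additive``.
3. Cross significantly above the high parent -> ``over_dominance``.
4. Cross significantly below the low parent -> ``under_dominance``.
5. Cross DE from exactly one parent -> dominance of the resembled parent
   (``dominance_F`` when the Cross tracks F, ``dominance_L`` when it
   tracks L); the sub-mode is ``enhancing`` when the resembled parent is
   the higher-expressed parent and ``suppressing`` otherwise.
6. Anything else -> ``non_additive_unresolved``.

Over/under-dominance is tested against the single relevant parent, and is
checked before dominance so the categories stay mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import ValidationError
from .de import CONTRASTS_FOR_GENE_LIST

REQUIRED_CONTRASTS = ("F_vs_L", "F_vs_Cross", "L_vs_Cross", "MPV_vs_Cross")

MODES = (
    "additive",
    "dominance_F",
    "dominance_L",
    "over_dominance",
    "under_dominance",
    "non_additive_unresolved",
    "untestable",
)

NON_ADDITIVE_MODES = (
    "dominance_F",
    "dominance_L",
    "over_dominance",
    "under_dominance",
    "non_additive_unresolved",
)


@dataclass(frozen=True)
class ContrastEvidence:
    """DE flag and direction of one contrast, oriented Cross-vs-other.

    ``log2fc > 0`` means the second group of the contrast (the Cross for
    the parent and MPV contrasts) is the higher one.
    """

    is_de: bool
    log2fc: float
    untestable: bool = False


@dataclass(frozen=True)
class InheritanceCall:
    gene_id: str
    mode: str
    sub_mode: str  # enhancing / suppressing / none
    mean_f: float
    mean_l: float
    mean_cross: float


def classify_gene(
    gene_id: str,
    contrasts: Mapping[str, ContrastEvidence],
    mean_f: float,
    mean_l: float,
    mean_cross: float,
) -> InheritanceCall:
    """Classify one gene from its four contrasts and group means."""
    missing = [k for k in REQUIRED_CONTRASTS if k not in contrasts]
    if missing:
        raise ValidationError(f"missing contrast(s) for {gene_id}: {missing}")
    fl = contrasts["F_vs_L"]
    fx = contrasts["F_vs_Cross"]
    lx = contrasts["L_vs_Cross"]
    mx = contrasts["MPV_vs_Cross"]

    if any(c.untestable for c in (fl, fx, lx, mx)):
        return InheritanceCall(gene_id, "untestable", "none", mean_f, mean_l, mean_cross)
    if not mx.is_de:
        return InheritanceCall(gene_id, "additive", "none", mean_f, mean_l, mean_cross)

    high_is_f = mean_f >= mean_l
    high_vs_cross = fx if high_is_f else lx
    low_vs_cross = lx if high_is_f else fx
    if high_vs_cross.is_de and high_vs_cross.log2fc > 0:
        return InheritanceCall(
            gene_id, "over_dominance", "none", mean_f, mean_l, mean_cross
        )
    if low_vs_cross.is_de and low_vs_cross.log2fc < 0:
        return InheritanceCall(
            gene_id, "under_dominance", "none", mean_f, mean_l, mean_cross
        )

    if fx.is_de != lx.is_de:
        if lx.is_de:  # similar to F, different from L
            mode = "dominance_F"
            sub = "enhancing" if mean_f > mean_l else "suppressing"
        else:  # similar to L, different from F
            mode = "dominance_L"
            sub = "enhancing" if mean_l > mean_f else "suppressing"
        return InheritanceCall(gene_id, mode, sub, mean_f, mean_l, mean_cross)

    return InheritanceCall(
        gene_id, "non_additive_unresolved", "none", mean_f, mean_l, mean_cross
    )


def _evidence_frame(table: pd.DataFrame) -> pd.DataFrame:
    return table[["is_de", "log2fc", "untestable"]]


def classify_all(
    contrast_tables: Mapping[str, pd.DataFrame],
    normalized: pd.DataFrame,
    groups: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every gene; return the call table and a summary.

    ``contrast_tables`` maps the four contrast names to tables produced by
    the DE engine (indexed by gene, oriented with the Cross — or, for
    F_vs_L, the L group — as group b).  The summary counts genes per mode
    and sub-mode and reports the non-additive fraction of the compiled DE
    gene list.
    """
    missing = [k for k in REQUIRED_CONTRASTS if k not in contrast_tables]
    if missing:
        raise ValidationError(f"missing contrast table(s): {missing}")
    genes = contrast_tables["MPV_vs_Cross"].index
    for name in REQUIRED_CONTRASTS:
        if not contrast_tables[name].index.equals(genes):
            raise ValidationError(f"contrast {name} covers a different gene universe")

    f_samples = [s for s, g in groups.items() if g == "F"]
    l_samples = [s for s, g in groups.items() if g == "L"]
    x_samples = [s for s, g in groups.items() if g in ("FL", "LF")]
    mean_f = normalized[f_samples].mean(axis=1)
    mean_l = normalized[l_samples].mean(axis=1)
    mean_x = normalized[x_samples].mean(axis=1)

    ev = {k: _evidence_frame(t) for k, t in contrast_tables.items()}
    rows = []
    for gene in genes:
        contrasts = {
            k: ContrastEvidence(
                bool(ev[k].at[gene, "is_de"]),
                float(ev[k].at[gene, "log2fc"]),
                bool(ev[k].at[gene, "untestable"]),
            )
            for k in REQUIRED_CONTRASTS
        }
        call = classify_gene(
            gene, contrasts, float(mean_f[gene]), float(mean_l[gene]), float(mean_x[gene])
        )
        rows.append(
            {
                "gene_id": gene,
                "mode": call.mode,
                "sub_mode": call.sub_mode,
                "mean_F": call.mean_f,
                "mean_L": call.mean_l,
                "mean_Cross": call.mean_cross,
            }
        )
    calls = pd.DataFrame(rows).set_index("gene_id")

    de_list = compile_de_gene_list(contrast_tables)
    in_list = calls.index.isin(sorted(de_list))
    non_add = calls["mode"].isin(NON_ADDITIVE_MODES)
    summary_rows = []
    for mode in MODES:
        sel = calls["mode"] == mode
        summary_rows.append(
            {
                "mode": mode,
                "n": int(sel.sum()),
                "n_enhancing": int((sel & (calls["sub_mode"] == "enhancing")).sum()),
                "n_suppressing": int((sel & (calls["sub_mode"] == "suppressing")).sum()),
            }
        )
    summary = pd.DataFrame(summary_rows)
    summary.attrs["de_gene_list_size"] = len(de_list)
    summary.attrs["non_additive_in_de_list"] = int((non_add & in_list).sum())
    summary.attrs["non_additive_fraction_of_de_list"] = (
        float((non_add & in_list).sum() / len(de_list)) if de_list else float("nan")
    )
    return calls, summary


def compile_de_gene_list(contrast_tables: Mapping[str, pd.DataFrame]) -> set[str]:
    """Union of DE genes over F vs L and the Cross-vs-{F, L, MPV} contrasts.

    The reciprocal FL vs LF contrast is deliberately excluded.
    """
    out: set[str] = set()
    for name in CONTRASTS_FOR_GENE_LIST:
        if name not in contrast_tables:
            raise ValidationError(f"missing contrast table: {name}")
        t = contrast_tables[name]
        out |= set(t.index[t["is_de"].astype(bool)])
    return out
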