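"""Core data containers and delimited-text I/O.

The pipeline's raw input is a gene x sample matrix of non-negative integer
read counts together with a sample metadata table assigning each sample to
one of the experimental groups: the two inbred parental lines (``F``,
Fayoumi-like; ``L``, Leghorn-like), the reciprocal F1 crosses (``FL``,
``LF``), and the synthetic mid-parent pseudo-group (``MPV``).  ``Cross`` is
a virtual group pooling the FL and LF samples.

All tables are tab-separated UTF-8 text with a mandatory header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: group labels a sample may carry
GROUP_LABELS = ("F", "L", "FL", "LF", "MPV")

#: the virtual group pooling both reciprocal crosses
CROSS = "Cross"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def group_samples(groups: Mapping[str, str], name: str) -> list[str]:
    """Sample ids belonging to a group; ``Cross`` pools FL and LF."""
    if name == CROSS:
        wanted = {"FL", "LF"}
    else:
        wanted = {name}
    return [s for s, g in groups.items() if g in wanted]


@dataclass(frozen=True)
class GroupSpec:
    """A named subset of samples used as one side of a contrast."""

    name: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValidationError(f"group {self.name!r} has no samples")


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) plus sample -> group labels.

    ``counts`` is a DataFrame indexed by gene id with one column per sample.
    Counts must be non-negative integers; gene and sample identifiers must be
    unique; every sample must have a group label.
    """

    counts: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(vals < 0):
            raise ValidationError("negative counts present")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("non-integer counts present")
        missing = [s for s in c.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in GROUP_LABELS}
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")
        self.counts = c.astype(np.int64)
        # keep only labels for samples actually present, in column order
        self.groups = {s: self.groups[s] for s in c.columns}

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return group_samples(self.groups, group)

    def group_spec(self, name: str) -> GroupSpec:
        return GroupSpec(name, tuple(self.samples_in(name)))

    def zero_genes(self) -> pd.Index:
        """Genes with zero counts in every sample (kept, but untestable)."""
        return self.counts.index[(self.counts == 0).all(axis=1)]


@dataclass
class AseTable:
    """Gene-level allele-specific-expression calls.

    One row per gene.  ``preferred_allele`` names the parental allele with
    the higher expression in the F1 (``F`` or ``L``); it is undefined for
    genes whose SNP-level calls conflict (``conflicting`` true), which are
    excluded from overlap analyses.
    """

    table: pd.DataFrame

    REQUIRED = ("gene_id", "preferred_allele", "conflicting")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"ASE table missing columns: {missing}")
        if t["gene_id"].duplicated().any():
            raise ValidationError("ASE table has duplicate gene ids")
        t = t.copy()
        t["conflicting"] = t["conflicting"].astype(bool)
        ok = t["conflicting"] | t["preferred_allele"].isin(["F", "L"])
        if not ok.all():
            raise ValidationError(
                "preferred_allele must be F or L for non-conflicting genes"
            )
        self.table = t.reset_index(drop=True)

    def preferred(self, allele: str) -> set[str]:
        """Non-conflicting genes preferring the given parental allele."""
        t = self.table
        sel = (~t["conflicting"]) & (t["preferred_allele"] == allele)
        return set(t.loc[sel, "gene_id"])

    def usable_genes(self) -> set[str]:
        return set(self.table.loc[~self.table["conflicting"], "gene_id"])


@dataclass
class PhenotypeTable:
    """Per-embryo egg and embryo weights (grams) with group labels."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "egg_weight", "embryo_weight")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in phenotype table")
        if not t["group"].isin(GROUP_LABELS).all():
            raise ValidationError("unknown group label in phenotype table")
        if (t["egg_weight"] <= 0).any() or (t["embryo_weight"] <= 0).any():
            raise ValidationError("weights must be positive")
        if (t["embryo_weight"] >= t["egg_weight"]).any():
            raise ValidationError("embryo weight must be below egg weight")
        self.table = t.reset_index(drop=True)

    def samples_in(self, group: str) -> pd.DataFrame:
        wanted = {"FL", "LF"} if group == CROSS else {group}
        return self.table[self.table["group"].isin(wanted)]


# ---------------------------------------------------------------------------
# delimited-text I/O (tab-separated, UTF-8, '.' decimal, header mandatory)
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a counts TSV (gene_id + one column per sample) and metadata TSV.

    The metadata file must have columns ``sample_id`` and ``group``.
    Validation errors are raised for duplicate identifiers, negative or
    non-integral counts, and samples absent from the metadata.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValidationError("metadata needs 'sample_id' and 'group' columns")
    groups = dict(zip(meta["sample_id"], meta["group"]))
    return CountMatrix(counts, groups)


def write_count_matrix(
    cm: CountMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {"sample_id": cm.sample_ids, "group": [cm.groups[s] for s in cm.sample_ids]}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_ase_table(path: str | Path) -> AseTable:
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return AseTable(t)


def write_ase_table(ase: AseTable, path: str | Path) -> None:
    ase.table.sort_values("gene_id").to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    return PhenotypeTable(t)


def write_phenotype_table(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)


def write_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as TSV with deterministic row order.

    Rows are sorted by ``gene_id`` when that column (or index name) exists;
    the header row is always written.
    """
    df = result.copy()
    if df.index.name == "gene_id":
        df = df.reset_index()
    if "gene_id" in df.columns:
        df = df.sort_values("gene_id", kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
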