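"""Mid-parent-value (MPV) pseudo-group construction.

The MPV is the additive expectation for the F1: per gene (or per trait),
the average of the two parental lines' values.  For expression data the
builder creates pseudo-samples on the normalized scale — one per (F, L)
sample pair — labeled group ``MPV`` and carrying size factor 1.  Two
pairing schemes are supported: a random perfect matching using each
parental sample at most once (min(nF, nL) pseudo-samples), and the full
Cartesian product of parental samples (nF x nL pseudo-samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .data_model import CountMatrix, PhenotypeTable, ValidationError, group_samples

Scheme = Literal["random_matching", "all_combinations"]


@dataclass(frozen=True)
class MpvPairing:
    """The (F sample, L sample) pairs behind each MPV pseudo-sample."""

    pairs: tuple[tuple[str, str], ...]
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError("pairing is empty")
        if self.scheme == "random_matching":
            f_used = [f for f, _ in self.pairs]
            l_used = [l for _, l in self.pairs]
            if len(set(f_used)) != len(f_used) or len(set(l_used)) != len(l_used):
                raise ValidationError(
                    "random_matching must use each parental sample at most once"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mpv_sample": [f"MPV_{i + 1}" for i in range(len(self.pairs))],
                "f_sample": [f for f, _ in self.pairs],
                "l_sample": [l for _, l in self.pairs],
            }
        )


def make_pairing(
    f_samples: list[str],
    l_samples: list[str],
    scheme: Scheme = "random_matching",
    seed: int = 0,
) -> MpvPairing:
    if not f_samples or not l_samples:
        raise ValidationError("both parental groups must be non-empty")
    rng = np.random.default_rng(seed)
    if scheme == "random_matching":
        k = min(len(f_samples), len(l_samples))
        f_perm = list(rng.permutation(f_samples))[:k]
        l_perm = list(rng.permutation(l_samples))[:k]
        pairs = tuple(zip(f_perm, l_perm))
    elif scheme == "all_combinations":
        pairs = tuple((f, l) for f in f_samples for l in l_samples)
    else:
        raise ValidationError(f"unknown pairing scheme: {scheme!r}")
    return MpvPairing(pairs, scheme, seed)


def build_mpv_expression(
    normalized: pd.DataFrame,
    groups: dict[str, str],
    scheme: Scheme = "all_combinations",
    seed: int = 0,
    pairing: MpvPairing | None = None,
) -> tuple[pd.DataFrame, dict[str, str], MpvPairing]:
    """Append MPV pseudo-samples to a normalized matrix.

    Each pseudo-sample is the elementwise arithmetic mean of one F and one
    L sample's normalized values, kept real-valued.  Returns the augmented
    matrix, the group map extended with the MPV labels, and the pairing.
    """
    f_samples = group_samples(groups, "F")
    l_samples = group_samples(groups, "L")
    if pairing is None:
        pairing = make_pairing(f_samples, l_samples, scheme=scheme, seed=seed)
    out = normalized.copy()
    new_groups = dict(groups)
    for i, (f, l) in enumerate(pairing.pairs):
        sid = f"MPV_{i + 1}"
        out[sid] = (normalized[f] + normalized[l]) / 2.0
        new_groups[sid] = "MPV"
    return out, new_groups, pairing


def round_mpv_for_counts(augmented: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Round MPV pseudo-sample values half-to-even for the NB contrast.

    The NB test consumes count-scale values; real samples are untouched.
    """
    out = augmented.copy()
    mpv_cols = [s for s, g in groups.items() if g == "MPV"]
    out[mpv_cols] = np.rint(out[mpv_cols])
    return out


def build_mpv_phenotype(
    phenotypes: PhenotypeTable, seed: int = 0
) -> tuple[pd.DataFrame, MpvPairing]:
    """Mid-parent egg and embryo weights from randomly paired F and L embryos.

    A random perfect matching up to min(nF, nL) pairs; each MPV row is the
    arithmetic mean of its pair's weights.  Deterministic given the seed.
    """
    t = phenotypes.table
    f = t[t["group"] == "F"]
    l = t[t["group"] == "L"]
    if f.empty or l.empty:
        raise ValidationError("both parental groups must be non-empty")
    pairing = make_pairing(
        list(f["sample_id"]), list(l["sample_id"]), scheme="random_matching", seed=seed
    )
    by_id = t.set_index("sample_id")
    rows = []
    for i, (fs, ls) in enumerate(pairing.pairs):
        rows.append(
            {
                "sample_id": f"MPV_ph{i + 1}",
                "group": "MPV",
                "egg_weight": (by_id.at[fs, "egg_weight"] + by_id.at[ls, "egg_weight"]) / 2.0,
                "embryo_weight": (
                    by_id.at[fs, "embryo_weight"] + by_id.at[ls, "embryo_weight"]
                )
                / 2.0,
            }
        )
    return pd.DataFrame(rows), pairing
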