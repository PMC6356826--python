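"""Correlation-distance K-means on stabilized log expression profiles.

Genes are clustered on their group-average log2(normalized + 1) profiles
(columns F, Cross, L by default) with distance ``1 - Pearson r``.  After
per-gene standardization (center, unit norm) this distance is half the
squared Euclidean distance, so Lloyd iterations with mean centroids
(renormalized) monotonically decrease the objective.  Genes with constant
profiles have no defined correlation and go to a dedicated overflow
cluster 0; real clusters are numbered 1..K.

The number of clusters can be screened with a leave-one-condition-out
figure of merit (FOM): for each left-out column, cluster on the remaining
columns and score the root-mean-square deviation of the left-out values
from their cluster means, adjusted by sqrt(n / (n - K)).  A knee in the
FOM curve (largest second difference) suggests K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ValidationError

DEFAULT_GROUP_ORDER = ("F", "Cross", "L")


def stabilized_log(normalized: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(value + pseudocount); input must be non-negative."""
    if (normalized.to_numpy() < 0).any():
        raise ValidationError("stabilized_log requires non-negative values")
    return np.log2(normalized + pseudocount)


def group_average_profiles(
    logmat: pd.DataFrame,
    groups: Mapping[str, str],
    order: Sequence[str] = DEFAULT_GROUP_ORDER,
) -> pd.DataFrame:
    """Average the per-sample columns into one column per group.

    ``Cross`` pools FL and LF samples.
    """
    cols = {}
    for g in order:
        if g == "Cross":
            samples = [s for s, lab in groups.items() if lab in ("FL", "LF")]
        else:
            samples = [s for s, lab in groups.items() if lab == g]
        samples = [s for s in samples if s in logmat.columns]
        if not samples:
            raise ValidationError(f"no samples for group {g}")
        cols[g] = logmat[samples].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass
class ClusterAssignment:
    """K-means result: per-gene cluster ids and per-cluster summaries.

    ``assignments`` maps gene -> cluster in 1..K (0 = overflow cluster of
    constant profiles).  ``objective_trace`` records the best restart's
    within-cluster total distance after each Lloyd iteration.
    """

    assignments: pd.Series
    k: int
    objective: float
    objective_trace: list[float]
    cluster_profiles: pd.DataFrame
    labels: pd.DataFrame | None = None


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; flag constant rows."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms < 1e-12
    safe = np.where(constant, 1.0, norms)
    return centered / safe[:, None], constant


def _lloyd(
    z: np.ndarray, k: int, init_idx: np.ndarray, max_iter: int = 100
) -> tuple[np.ndarray, float, list[float]]:
    """Spherical Lloyd iterations on standardized profiles.

    Distance to a centroid is ``1 - z . c_hat`` with the centroid the
    (renormalized) mean of its members' standardized profiles.  Ties in
    assignment go to the lowest cluster index.  Returns (labels 0..k-1,
    objective, per-iteration objective trace).
    """
    centroids = z[init_idx].copy()

    def _norm_rows(c: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(c, axis=1, keepdims=True)
        return np.divide(c, np.where(n < 1e-12, 1.0, n))

    centroids = _norm_rows(centroids)
    labels = np.full(len(z), -1)
    trace: list[float] = []
    for _ in range(max_iter):
        sims = z @ centroids.T  # cosine == Pearson r of the raw profiles
        new_labels = np.argmax(sims, axis=1)  # argmax takes lowest index on ties
        obj = float((1.0 - sims[np.arange(len(z)), new_labels]).sum())
        trace.append(obj)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = z[labels == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
        centroids = _norm_rows(centroids)
    sims = z @ centroids.T
    obj = float((1.0 - sims[np.arange(len(z)), labels]).sum())
    return labels, obj, trace


def kmeans_correlation(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Best-of-restarts K-means under Pearson correlation distance."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    x = profiles.to_numpy(dtype=float)
    z, constant = _standardize(x)
    usable = np.where(~constant)[0]
    if len(usable) < k:
        raise ValidationError(f"k={k} exceeds the {len(usable)} usable genes")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list[float]] | None = None
    for _ in range(restarts):
        init = rng.choice(len(usable), size=k, replace=False)
        labels, obj, trace = _lloyd(z[usable], k, init, max_iter)
        if best is None or obj < best[1] - 1e-12:
            best = (labels, obj, trace)
    labels, obj, trace = best

    assignments = pd.Series(0, index=profiles.index, name="cluster")
    assignments.iloc[usable] = labels + 1

    prof_rows = {}
    for j in range(1, k + 1):
        members = profiles.index[assignments == j]
        if len(members):
            prof_rows[j] = profiles.loc[members].mean(axis=0)
        else:
            prof_rows[j] = pd.Series(np.nan, index=profiles.columns)
    cluster_profiles = pd.DataFrame(prof_rows).T
    cluster_profiles.index.name = "cluster"
    return ClusterAssignment(assignments, k, obj, trace, cluster_profiles)


def figure_of_merit(
    profiles: pd.DataFrame,
    k_range: Sequence[int],
    seed: int = 0,
    restarts: int = 10,
) -> tuple[pd.DataFrame, int]:
    """Leave-one-condition-out FOM curve and a knee-based K suggestion.

    For each left-out column, genes are clustered on the remaining columns
    and the FOM is the adjusted RMS deviation of the left-out values from
    their cluster means; the curve sums over left-out columns.  The
    suggested K maximizes the second difference of the curve (the knee);
    the first K is returned when the curve has no interior point.
    """
    if profiles.shape[1] < 3:
        raise ValidationError("FOM needs at least 3 condition columns")
    n = len(profiles)
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k >= n for k in ks):
        raise ValidationError("each K must satisfy 2 <= K < n_genes")
    rows = []
    for k in ks:
        total = 0.0
        for left_out in profiles.columns:
            rest = profiles.drop(columns=[left_out])
            res = kmeans_correlation(rest, k, seed=seed, restarts=restarts)
            y = profiles[left_out]
            sq = 0.0
            for j in range(0, k + 1):
                members = res.assignments.index[res.assignments == j]
                if len(members) == 0:
                    continue
                dev = y.loc[members] - y.loc[members].mean()
                sq += float((dev**2).sum())
            rms = np.sqrt(sq / n)
            total += rms / np.sqrt((n - k) / n)
        rows.append({"k": k, "fom": total})
    curve = pd.DataFrame(rows)
    fom = curve["fom"].to_numpy()
    if len(ks) >= 3:
        second_diff = fom[:-2] - 2 * fom[1:-1] + fom[2:]
        suggested = ks[1 + int(np.argmax(second_diff))]
    else:
        suggested = ks[0]
    return curve, suggested


def label_clusters(
    assignment: ClusterAssignment, calls: pd.DataFrame
) -> ClusterAssignment:
    """Label each cluster additive / non-additive by its gene composition.

    The non-additive fraction is the share of member genes whose
    inheritance mode is non-additive; a cluster is labeled non-additive
    only when that share strictly exceeds 0.5.  Empty clusters are
    excluded.  Every clustered gene must have a call.
    """
    from .classifier import NON_ADDITIVE_MODES

    genes = assignment.assignments.index
    missing = genes.difference(calls.index)
    if len(missing):
        raise ValidationError(f"genes without inheritance calls: {list(missing[:5])}")
    non_add = calls.loc[genes, "mode"].isin(NON_ADDITIVE_MODES)
    rows = []
    for j in sorted(assignment.assignments.unique()):
        members = genes[assignment.assignments == j]
        if len(members) == 0:
            continue
        frac = float(non_add.loc[members].mean())
        rows.append(
            {
                "cluster": j,
                "n_genes": len(members),
                "non_additive_fraction": frac,
                "label": "non-additive" if frac > 0.5 else "additive",
            }
        )
    labeled = ClusterAssignment(
        assignment.assignments,
        assignment.k,
        assignment.objective,
        assignment.objective_trace,
        assignment.cluster_profiles,
        labels=pd.DataFrame(rows),
    )
    return labeled
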