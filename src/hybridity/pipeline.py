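"""End-to-end orchestration: normalize -> contrasts -> classify -> cluster
-> ASE overlap -> phenotype, with a manifest of outputs.

``run_de_suite`` is the analysis core shared by the pipeline, the CLI, and
the test harness: it computes size factors once, builds the MPV
pseudo-group, and runs the five pairwise contrasts (F vs L, F vs Cross,
L vs Cross, FL vs LF, MPV vs Cross) on the shared normalized matrix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .ase_overlap import ase_de_fraction, build_overlap, chi2_independence
from .classifier import classify_all, compile_de_gene_list
from .clustering import (
    figure_of_merit,
    group_average_profiles,
    kmeans_correlation,
    label_clusters,
    stabilized_log,
)
from .data_model import (
    AseTable,
    CountMatrix,
    ValidationError,
    read_ase_table,
    read_count_matrix,
    read_phenotype_table,
    write_table,
)
from .de import (
    estimate_dispersion,
    finish_contrast,
    moderate_dispersion,
    normalize,
    size_factors,
    wald_contrast,
)
from .mpv import build_mpv_expression, round_mpv_for_counts
from .phenotype import summarize_phenotypes

log = logging.getLogger("hybridity")

CONTRAST_PLAN = (
    ("F_vs_L", "F", "L"),
    ("F_vs_Cross", "F", "Cross"),
    ("L_vs_Cross", "L", "Cross"),
    ("FL_vs_LF", "FL", "LF"),
    ("MPV_vs_Cross", "MPV", "Cross"),
)


@dataclass
class DeSuite:
    """All per-contrast tables plus the shared normalized matrix."""

    contrasts: dict[str, pd.DataFrame]
    normalized: pd.DataFrame  # includes real-valued MPV pseudo-samples
    groups: dict[str, str]  # includes MPV labels
    factors: pd.Series
    pairing: pd.DataFrame


def run_de_suite(
    cm: CountMatrix,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudocount: float = 0.5,
    mpv_scheme: str = "all_combinations",
    mpv_seed: int = 0,
    moderate: bool = True,
    prior_df: float = 10.0,
) -> DeSuite:
    """Normalize once, build the MPV group, and run the five contrasts."""
    factors = size_factors(cm.counts)
    norm = normalize(cm.counts, factors)
    augmented, groups, pairing = build_mpv_expression(
        norm, cm.groups, scheme=mpv_scheme, seed=mpv_seed
    )
    for_counts = round_mpv_for_counts(augmented, groups)

    def _samples(name: str) -> list[str]:
        if name == "Cross":
            return [s for s, g in groups.items() if g in ("FL", "LF")]
        return [s for s, g in groups.items() if g == name]

    contrasts: dict[str, pd.DataFrame] = {}
    for name, a, b in CONTRAST_PLAN:
        ga, gb = _samples(a), _samples(b)
        if not ga or not gb:
            raise ValidationError(f"contrast {name}: empty group")
        mat = for_counts if a == "MPV" or b == "MPV" else augmented
        gmap = {a: ga, b: gb}
        disp = estimate_dispersion(mat, {g: s for g, s in gmap.items() if len(s) >= 2})
        if moderate:
            residual_df = sum(len(s) - 1 for s in gmap.values() if len(s) >= 2)
            disp = moderate_dispersion(disp, residual_df, prior_df)
        res = wald_contrast(mat, gmap, a, b, disp["alpha"], pseudocount)
        contrasts[name] = finish_contrast(res, alpha=alpha, lfc_min=lfc_min)
        log.info("contrast %s: %d DE genes", name, int(contrasts[name]["is_de"].sum()))
    return DeSuite(contrasts, augmented, groups, factors, pairing.to_frame())


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    counts: str | None = None
    samples: str | None = None
    ase: str | None = None
    phenotypes: str | None = None
    out_dir: str = "results"
    alpha: float = 0.05
    lfc_min: float = 1.0
    pseudocount: float = 0.5
    mpv_scheme: str = "all_combinations"
    mpv_seed: int = 17
    cluster_k: int = 12
    cluster_restarts: int = 20
    cluster_seed: int = 7
    run_fom: bool = False
    fom_range: tuple[int, int] = (2, 20)
    phenotype_mpv_seed: int = 17

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.lfc_min < 0:
            raise ValidationError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fom_range" in data:
            data["fom_range"] = tuple(data["fom_range"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, cm: CountMatrix | None = None) -> dict:
    """Run every stage in dependency order and write a manifest.

    A :class:`CountMatrix` may be passed directly (e.g. from the
    simulator); otherwise it is read from ``config.counts`` /
    ``config.samples``.  Stages with missing optional inputs (ASE,
    phenotypes) are skipped and logged.  Returns the manifest dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / ".incomplete"
    marker.write_text("run in progress\n")
    outputs: list[Path] = []

    def _emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        write_table(df, path)
        outputs.append(path)

    try:
        if cm is None:
            if not config.counts or not config.samples:
                raise ValidationError("counts and samples paths are required")
            cm = read_count_matrix(config.counts, config.samples)
        log.info("loaded %d genes x %d samples", len(cm.gene_ids), len(cm.sample_ids))

        suite = run_de_suite(
            cm,
            alpha=config.alpha,
            lfc_min=config.lfc_min,
            pseudocount=config.pseudocount,
            mpv_scheme=config.mpv_scheme,
            mpv_seed=config.mpv_seed,
        )
        for name, table in suite.contrasts.items():
            _emit(table.reset_index(names="gene_id"), f"de_{name}.tsv")
        _emit(suite.pairing, "mpv_pairs.tsv")

        calls, summary = classify_all(
            {k: v for k, v in suite.contrasts.items() if k != "FL_vs_LF"},
            suite.normalized,
            suite.groups,
        )
        _emit(calls.reset_index(), "calls.tsv")
        _emit(summary, "summary.tsv")

        de_list = compile_de_gene_list(suite.contrasts)
        logmat = stabilized_log(suite.normalized)
        profiles = group_average_profiles(logmat, suite.groups)
        cluster_info: dict = {}
        de_profiles = profiles.loc[sorted(de_list)] if de_list else profiles.iloc[:0]
        if len(de_list) > config.cluster_k:
            if config.run_fom:
                lo, hi = config.fom_range
                curve, suggested = figure_of_merit(
                    de_profiles,
                    range(lo, min(hi, len(de_list) - 1) + 1),
                    seed=config.cluster_seed,
                    restarts=config.cluster_restarts,
                )
                _emit(curve, "fom.tsv")
                cluster_info["fom_suggested_k"] = suggested
            assignment = kmeans_correlation(
                de_profiles,
                config.cluster_k,
                seed=config.cluster_seed,
                restarts=config.cluster_restarts,
            )
            labeled = label_clusters(assignment, calls)
            _emit(
                labeled.assignments.rename("cluster").reset_index(), "clusters.tsv"
            )
            _emit(labeled.labels, "cluster_labels.tsv")
            cluster_info["k"] = config.cluster_k
        else:
            log.info("clustering skipped: only %d DE genes", len(de_list))

        overlap_info: dict = {}
        if config.ase:
            ase = read_ase_table(config.ase)
            overlap = build_overlap(calls, ase, de_list)
            _emit(
                overlap.table.reset_index(names="category"), "overlap.tsv"
            )
            frac = ase_de_fraction(overlap, de_list)
            chi2 = chi2_independence(
                de_list,
                overlap.sets["ASE_F"] | overlap.sets["ASE_L"],
                universe=calls.index[calls["mode"] != "untestable"],
            )
            overlap_info = {
                "ase_de_fraction": frac,
                "chi2_statistic": chi2.statistic,
                "chi2_p": chi2.p,
            }
        else:
            log.info("ASE overlap skipped: no ASE table provided")

        if config.phenotypes:
            pheno = read_phenotype_table(config.phenotypes)
            ps = summarize_phenotypes(pheno, mpv_seed=config.phenotype_mpv_seed)
            _emit(ps.group_stats, "pheno_summary.tsv")
            comp = pd.concat(
                [r.comparisons.assign(variable=v) for v, r in ps.results.items()],
                ignore_index=True,
            )
            _emit(comp, "pheno_comparisons.tsv")
        else:
            log.info("phenotype stage skipped: no phenotype table provided")

        manifest = {
            "version": __version__,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
            "de_gene_list_size": len(de_list),
            "non_additive_fraction_of_de_list": summary.attrs[
                "non_additive_fraction_of_de_list"
            ],
            "cluster": cluster_info,
            "overlap": overlap_info,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        marker.unlink()
        return manifest
    except Exception:
        log.exception("pipeline run failed; partial outputs retained in %s", out_dir)
        raise
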