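"""End-to-end orchestration: ingest -> preprocess -> impute -> cluster ->
characterize -> predict, from one configuration, with deterministic text
artifacts and a run manifest.

A single master seed is expanded through ``numpy.random.SeedSequence`` into
independent per-stage seeds; no stage touches global random state.  All
artifacts are plain delimited or structured text so runs diff cleanly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characterize import (
    cluster_mean_effects,
    cluster_mean_scores,
    component_receptor_loadings,
    correlate_components_with_effects,
)
from .cluster import build_graph, correlation_matrix, louvain_partition
from .ingest import (
    AgonismTable,
    GroupingScheme,
    build_affinity_matrix,
    filter_human,
    parse_agonism_table,
    parse_clinical_table,
    parse_grouping,
    parse_ki_table,
)
from .ppca import fit_ppca, impute, scores, variance_explained
from .predict import PredictionReport, encode_predictors, permutation_test
from .preprocess import apply_agonism_inversion, floor_adjust
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_all", "compare_schemes"]


@dataclass
class RunConfig:
    """Configuration for one full pipeline run.

    Exactly one of ``synthetic`` or ``ki_path`` must be set.  All seeds are
    derived from ``seed``; nothing is wall-clock seeded.
    """

    outdir: str | Path = "run_output"
    seed: int = 0
    # real inputs
    ki_path: str | Path | None = None
    agonism_path: str | Path | None = None
    clinical_path: str | Path | None = None
    grouping_paths: dict[str, str] = field(default_factory=dict)
    # or a synthetic study
    synthetic: SyntheticConfig | None = None
    # stage parameters
    min_drugs_per_receptor: int = 5
    min_receptors_per_drug: int = 5
    floor: float = 4.0
    q: int = 5
    negative_policy: str = "clip_zero"
    n_restarts: int = 100
    n_perm: int = 500
    n_components: int = 2
    q_impute: int = 2
    k_top: int = 3

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.ki_path is None):
            raise ValueError("set exactly one of synthetic config or ki_path")


@dataclass
class RunResult:
    partition: object
    reports: dict[str, PredictionReport]
    manifest: dict
    outdir: Path


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["ppca", "cluster", "predict", "synthetic"])
    warnings: list[str] = []

    # ---- ingest
    if config.synthetic is not None:
        synth_cfg = config.synthetic
        dataset = generate(synth_cfg)
        records = filter_human(dataset.records)
        agonism = dataset.agonism
        clinical = dataset.clinical
        schemes = dict(dataset.schemes)
    else:
        records = filter_human(parse_ki_table(config.ki_path))
        agonism = (
            parse_agonism_table(config.agonism_path)
            if config.agonism_path
            else None
        )
        if config.clinical_path is None:
            raise ValueError("clinical_path is required for real-data runs")
        clinical = parse_clinical_table(config.clinical_path)
        schemes = {
            name: parse_grouping(path, name)
            for name, path in config.grouping_paths.items()
        }
    affinity = build_affinity_matrix(
        records,
        min_drugs_per_receptor=config.min_drugs_per_receptor,
        min_receptors_per_drug=config.min_receptors_per_drug,
    )
    affinity.to_tsv(outdir / "affinity_pki.tsv")

    # ---- preprocess
    floored = floor_adjust(affinity, floor=config.floor)
    adjusted = apply_agonism_inversion(
        floored, agonism if agonism is not None else AgonismTable(),
        floor_constant=config.floor,
    )
    adjusted.to_tsv(outdir / "adjusted.tsv")

    # ---- impute + components
    model = fit_ppca(
        adjusted.values, q=config.q, mask=adjusted.observed, seed=seeds["ppca"]
    )
    completed_values = impute(model, adjusted.values, adjusted.observed)
    completed = adjusted.completed(completed_values)
    completed.to_tsv(outdir / "completed.tsv")
    drug_scores = scores(model, completed.values)
    var_frac = variance_explained(model, completed.values)

    # ---- cluster
    sim = correlation_matrix(completed)
    sim.to_tsv(outdir / "similarity.tsv")
    graph = build_graph(sim, negative_policy=config.negative_policy)
    partition = louvain_partition(
        graph, seed=seeds["cluster"], n_restarts=config.n_restarts
    )
    partition.to_tsv(outdir / "partition.tsv")

    # ---- characterize
    k_top = min(config.k_top, config.q)
    cluster_scores = cluster_mean_scores(drug_scores, completed.drugs, partition, k=k_top)
    cluster_scores.to_csv(outdir / "cluster_mean_scores.tsv", sep="\t")
    loadings = component_receptor_loadings(model, completed.receptors, k=k_top)
    loadings.to_csv(outdir / "component_receptor_loadings.tsv", sep="\t")
    corr, corr_n = correlate_components_with_effects(
        drug_scores, completed.drugs, clinical, k=k_top
    )
    corr.to_csv(outdir / "component_effect_correlations.tsv", sep="\t")
    effect_means, effect_counts = cluster_mean_effects(clinical, partition)
    effect_means.to_csv(outdir / "cluster_mean_effects.tsv", sep="\t")

    # ---- predict: derived clusters, every supplied scheme, full fingerprints
    derived = GroupingScheme(
        name="derived_clusters",
        assignment={d: f"cluster_{c}" for d, c in partition.assignment.items()},
    )
    predictor_sources = {"derived_clusters": derived, **schemes}
    reports: dict[str, PredictionReport] = {}
    for name, scheme in predictor_sources.items():
        reports[name] = permutation_test(
            encode_predictors(scheme),
            clinical,
            n_perm=config.n_perm,
            seed=seeds["predict"],
            n_components=config.n_components,
            q_impute=config.q_impute,
        )
    reports["receptor_profile"] = permutation_test(
        encode_predictors(completed),
        clinical,
        n_perm=config.n_perm,
        seed=seeds["predict"],
        n_components=config.n_components,
        q_impute=config.q_impute,
    )
    ranking = compare_schemes(list(reports.values()))
    ranking.to_csv(outdir / "scheme_comparison.tsv", sep="\t", index=False)
    for name, report in reports.items():
        pd.DataFrame({"null_median_error": report.null_median_errors}).to_csv(
            outdir / f"null_{name}.tsv", sep="\t", index=False
        )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            "min_drugs_per_receptor": config.min_drugs_per_receptor,
            "min_receptors_per_drug": config.min_receptors_per_drug,
            "floor": config.floor,
            "q": config.q,
            "negative_policy": config.negative_policy,
            "n_restarts": config.n_restarts,
            "n_perm": config.n_perm,
            "n_components": config.n_components,
            "q_impute": config.q_impute,
            "k_top": config.k_top,
        },
        "synthetic": None
        if config.synthetic is None
        else {k: getattr(config.synthetic, k) for k in vars(config.synthetic)},
        "inputs": {
            "ki_path": str(config.ki_path) if config.ki_path else None,
            "clinical_path": str(config.clinical_path) if config.clinical_path else None,
            "agonism_path": str(config.agonism_path) if config.agonism_path else None,
            "grouping_paths": {k: str(v) for k, v in config.grouping_paths.items()},
        },
        "results": {
            "n_drugs": len(completed.drugs),
            "n_receptors": len(completed.receptors),
            "n_clusters": partition.n_clusters,
            "modularity": partition.modularity,
            "variance_explained": [float(v) for v in var_frac],
            "ppca_converged": model.converged,
            "ppca_n_iter": model.n_iter,
            "schemes": {
                name: {
                    "D": r.D,
                    "observed_median_error": r.observed_median_error,
                    "p_value": r.p_value,
                }
                for name, r in reports.items()
            },
        },
        "warnings": warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(partition=partition, reports=reports, manifest=manifest, outdir=outdir)


def compare_schemes(reports: list[PredictionReport]) -> pd.DataFrame:
    """Rank prediction reports by observed median error (ascending).

    All reports must cover the same drugs; ties are broken by scheme name.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    drug_sets = {frozenset(r.per_drug_errors) for r in reports}
    if len(drug_sets) != 1:
        raise ValueError("reports cover different drug sets; cannot rank")
    rows = sorted(
        (
            {
                "scheme": r.scheme,
                "D": r.D,
                "observed_median_error": r.observed_median_error,
                "p_value": r.p_value,
            }
            for r in reports
        ),
        key=lambda row: (row["observed_median_error"], row["scheme"]),
    )
    return pd.DataFrame(rows)
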