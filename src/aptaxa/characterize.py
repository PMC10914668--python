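"""Pharmacological and clinical characterization of drug clusters.

Given the fitted PPCA of receptor fingerprints and a partition of drugs,
summarize each cluster by its mean score on the leading components, map
components back to receptors through their loading vectors, correlate
component scores with clinical effects across drugs, and tabulate cluster
mean clinical effect scores.  Missing clinical cells are excluded from means
and correlations; no imputation happens at this stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cluster import Partition
from .ingest import ClinicalProfile
from .ppca import PPCAModel

logger = logging.getLogger(__name__)

__all__ = [
    "cluster_mean_scores",
    "component_receptor_loadings",
    "correlate_components_with_effects",
    "cluster_mean_effects",
]


def cluster_mean_scores(
    score_matrix: np.ndarray,
    drugs: list[str],
    partition: Partition,
    k: int = 3,
) -> pd.DataFrame:
    """Per-cluster mean of member drugs' scores on the top-k components."""
    score_matrix = np.asarray(score_matrix, dtype=float)
    if k > score_matrix.shape[1]:
        raise ValueError(f"k={k} exceeds available components {score_matrix.shape[1]}")
    labels = partition.labels(drugs)
    rows = {}
    for cid in sorted(set(labels)):
        members = labels == cid
        if not members.any():
            raise ValueError(f"cluster {cid} has no members among supplied drugs")
        rows[cid] = score_matrix[members, :k].mean(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = [f"component_{i + 1}" for i in range(k)]
    out.index.name = "cluster_id"
    return out


def component_receptor_loadings(
    model: PPCAModel, receptors: list[str], k: int = 3
) -> pd.DataFrame:
    """Sign-fixed receptor loading vectors for the top-k components."""
    if k > model.q:
        raise ValueError(f"k={k} exceeds model components q={model.q}")
    u, _ = model.principal_axes()
    out = pd.DataFrame(
        u[:, :k], index=receptors, columns=[f"component_{i + 1}" for i in range(k)]
    )
    out.index.name = "receptor"
    return out


def correlate_components_with_effects(
    score_matrix: np.ndarray,
    drugs: list[str],
    clinical: ClinicalProfile,
    k: int = 3,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r between per-drug component scores and clinical effects.

    Returns (correlations, n_used): k x n_effects tables.  A cell is NaN when
    fewer than ``min_pairs`` drugs have the effect observed, or when either
    variable is constant over the complete pairs (undefined correlation).
    """
    score_matrix = np.asarray(score_matrix, dtype=float)[:, :k]
    clin = clinical.subset([d for d in drugs if d in clinical.drugs])
    if clin.drugs != list(drugs):
        keep = [i for i, d in enumerate(drugs) if d in clin.drugs]
        score_matrix = score_matrix[keep]
    r = np.full((k, len(clin.effects)), np.nan)
    n_used = np.zeros((k, len(clin.effects)), dtype=int)
    for e in range(len(clin.effects)):
        obs = clin.observed[:, e]
        y = clin.scores[obs, e]
        for c in range(k):
            x = score_matrix[obs, c]
            n_used[c, e] = obs.sum()
            if obs.sum() < min_pairs:
                logger.warning(
                    "effect %r: only %d complete pairs (<%d); correlation masked",
                    clin.effects[e], int(obs.sum()), min_pairs,
                )
                continue
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r[c, e] = np.corrcoef(x, y)[0, 1]
    comp_names = [f"component_{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(r, index=comp_names, columns=clin.effects),
        pd.DataFrame(n_used, index=comp_names, columns=clin.effects),
    )


def cluster_mean_effects(
    clinical: ClinicalProfile, partition: Partition
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster mean clinical effect scores over observed member values.

    Returns (means, counts).  A (cluster, effect) cell with no observed member
    values is NaN with count 0.
    """
    drugs = [d for d in clinical.drugs if d in partition.assignment]
    clin = clinical.subset(drugs)
    labels = clin_labels = partition.labels(drugs)
    cluster_ids = sorted(set(clin_labels))
    means = np.full((len(cluster_ids), len(clin.effects)), np.nan)
    counts = np.zeros((len(cluster_ids), len(clin.effects)), dtype=int)
    for row, cid in enumerate(cluster_ids):
        member = labels == cid
        for e in range(len(clin.effects)):
            obs = member & clin.observed[:, e]
            counts[row, e] = obs.sum()
            if obs.any():
                means[row, e] = clin.scores[obs, e].mean()
    idx = pd.Index(cluster_ids, name="cluster_id")
    return (
        pd.DataFrame(means, index=idx, columns=clin.effects),
        pd.DataFrame(counts, index=idx, columns=clin.effects),
    )
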