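"""Shared fixtures: small hand-built record sets and one cached benchmark run."""

from __future__ import annotations

import numpy as np
import pytest

from aptaxa import (
    KiRecord,
    apply_agonism_inversion,
    build_affinity_matrix,
    correlation_matrix,
    filter_human,
    fit_ppca,
    floor_adjust,
    impute,
    louvain_partition,
    build_graph,
)
from aptaxa.synthetic import benchmark_dataset


def make_records(cells: dict[tuple[str, str], float], species: str = "human") -> list[KiRecord]:
    """Build one KiRecord per (drug, receptor) -> Ki_nM cell."""
    return [
        KiRecord(drug=d, receptor=r, species=species, ki_nM=ki, source_id=f"{d}:{r}")
        for (d, r), ki in cells.items()
    ]


@pytest.fixture(scope="session")
def benchmark():
    """One reference-shaped synthetic study (27 drugs x 42 receptors)."""
    return benchmark_dataset(seed=1)


@pytest.fixture(scope="session")
def benchmark_completed(benchmark):
    """The benchmark study taken through ingest -> adjust -> impute -> cluster."""
    affinity = build_affinity_matrix(filter_human(benchmark.records))
    adjusted = apply_agonism_inversion(floor_adjust(affinity), benchmark.agonism)
    model = fit_ppca(adjusted.values, q=5, mask=adjusted.observed, seed=0)
    completed = adjusted.completed(impute(model, adjusted.values, adjusted.observed))
    partition = louvain_partition(
        build_graph(correlation_matrix(completed)), seed=0, n_restarts=50
    )
    return {
        "affinity": affinity,
        "adjusted": adjusted,
        "model": model,
        "completed": completed,
        "partition": partition,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
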