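"""Synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the shape of the real inputs: a long-format table of
replicate Ki measurements on human tissue, a (drug, receptor) agonism
annotation table, a drug x effect clinical score table, and categorical
grouping schemes.  Drug fingerprints are drawn from planted cluster centers
laid out as vertices of a regular simplex (so "separation" — the pairwise
center distance in units of the within-cluster standard deviation — has one
interpretable meaning) plus isotropic Gaussian noise on the pKi scale.
Observed cells are mapped back to Ki records through Ki = 10^(9 - pKi), with
replicate measurements scattered log-normally so that median aggregation is
exercised on the Ki scale.  Missingness is MCAR; agonism flags are planted
per (cluster, receptor) so that functionally inverse action is shared by a
cluster, as it is for real drug classes.  Clinical effects are a noisy linear
function of either cluster membership or the adjusted receptor profile.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ingest import AgonismTable, ClinicalProfile, GroupingScheme, KiRecord

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticDataset", "generate", "benchmark_dataset"]

SIDE_EFFECT_NAMES = [
    "weight_gain", "parkinsonism", "akathisia", "anticholinergic", "sedation",
    "hyperprolactinaemia", "qtc_prolongation", "postural_hypotension",
    "dystonia", "tardive_dyskinesia", "seizure", "dyslipidaemia", "dysglycaemia",
]
EFFICACY_NAMES = ["efficacy_total", "efficacy_positive", "efficacy_negative"]


@dataclass
class SyntheticConfig:
    n_drugs: int = 27
    n_receptors: int = 42
    n_clusters: int = 4
    separation: float = 8.0       # center distance / within-cluster sd
    noise_sd: float = 0.5         # within-cluster fingerprint sd, pKi units
    missing_rate: float = 0.2     # MCAR cell deletion probability
    agonist_fraction: float = 0.0  # per (cluster, receptor) flip probability
    effect_link: str = "group"    # "group" | "profile"
    effect_scale: float = 1.0     # sd of true between-group effect differences
    effect_noise_sd: float = 0.5  # residual sd of clinical scores
    n_effects: int = 16
    records_per_cell: int = 1
    replicate_log10_sd: float = 0.1  # scatter of replicate Ki measurements
    pki_floor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_drugs:
            raise ValueError("n_clusters cannot exceed n_drugs")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_link not in ("group", "profile"):
            raise ValueError("effect_link must be 'group' or 'profile'")
        if self.records_per_cell < 1:
            raise ValueError("records_per_cell must be >= 1")


@dataclass
class SyntheticTruth:
    partition: dict[str, int]
    cluster_centers: np.ndarray         # K x p, pKi scale
    complete_pki: np.ndarray            # n x p pre-missingness fingerprints
    observed: np.ndarray                # MCAR mask actually released
    inverted_receptors: dict[int, list[str]]  # cluster -> agonism-flagged receptors
    effect_coefficients: np.ndarray     # K x k (group link) or p x k (profile link)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    records: list[KiRecord]
    agonism: AgonismTable
    clinical: ClinicalProfile
    schemes: dict[str, GroupingScheme]
    truth: SyntheticTruth
    drugs: list[str] = field(default_factory=list)
    receptors: list[str] = field(default_factory=list)


def _simplex_vertices(k: int) -> np.ndarray:
    """k equidistant unit-pairwise-distance points in (k-1) dimensions."""
    if k == 1:
        return np.zeros((1, 1))
    eye = np.eye(k)
    centered = eye - eye.mean(axis=0)
    # pairwise distance of centered identity columns is sqrt(2)
    coords = centered / np.sqrt(2.0)
    u, s, _ = np.linalg.svd(coords, full_matrices=False)
    return (u * s)[:, : k - 1]


def _effect_names(k: int) -> tuple[list[str], list[str]]:
    if k == 16:
        names = SIDE_EFFECT_NAMES + EFFICACY_NAMES
    else:
        n_eff = min(3, max(0, k - 1)) if k > 3 else 0
        names = [f"side_effect_{i + 1:02d}" for i in range(k - n_eff)] + EFFICACY_NAMES[:n_eff]
    kinds = ["efficacy" if n.startswith("efficacy") else "side_effect" for n in names]
    return names, kinds


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete synthetic study from the planted-cluster model."""
    rng = np.random.default_rng(config.seed)
    n, p, K = config.n_drugs, config.n_receptors, config.n_clusters
    drugs = [f"drug_{i + 1:02d}" for i in range(n)]
    receptors = [f"R{j + 1:02d}" for j in range(p)]

    # balanced cluster assignment, then shuffled so order carries no signal
    labels = np.array([i % K for i in range(n)])
    rng.shuffle(labels)

    # cluster centers: regular simplex embedded in receptor space
    # The between-cluster offsets carry the signal; the shared baseline is a
    # mid-range pKi with mild per-receptor jitter.  A strongly heterogeneous
    # shared baseline would dominate the drug-drug Pearson correlations and
    # mask the planted structure that "separation" is meant to control.
    unit = config.noise_sd if config.noise_sd > 0 else 1.0
    simplex = _simplex_vertices(K) * config.separation * unit
    basis = np.linalg.qr(rng.standard_normal((p, max(K - 1, 1))))[0]
    base = 6.5 + 0.25 * rng.standard_normal(p)
    centers = base[None, :] + simplex @ basis.T
    lift = config.pki_floor + 0.2 - centers.min()
    if lift > 0:
        centers = centers + lift

    complete = centers[labels] + config.noise_sd * rng.standard_normal((n, p))

    # MCAR mask; rejection-resample until every row and column keeps data
    observed = np.ones((n, p), dtype=bool)
    if config.missing_rate > 0:
        for _ in range(200):
            observed = rng.random((n, p)) >= config.missing_rate
            if observed.any(axis=1).all() and observed.any(axis=0).all():
                break
        else:
            raise RuntimeError("could not draw a feasible MCAR mask; lower missing_rate")

    # agonism flags shared within a cluster and disjoint across clusters:
    # each class partial-agonizes its own receptors, as real drug classes do
    # (a shared flipped receptor would spuriously correlate two classes)
    inverted: dict[int, list[str]] = {c: [] for c in range(K)}
    entries: dict[tuple[str, str], str] = {}
    if config.agonist_fraction > 0:
        pool = list(rng.permutation(p))
        for c in range(K):
            n_flag = int(rng.binomial(p, config.agonist_fraction))
            take, pool = pool[:n_flag], pool[n_flag:]
            inverted[c] = [receptors[j] for j in sorted(take)]
        for i, d in enumerate(drugs):
            for j, rec in enumerate(receptors):
                if rec in inverted[labels[i]]:
                    mode = "partial_agonist" if rng.random() < 0.5 else "agonist"
                    entries[(d, rec.lower())] = mode
    agonism = AgonismTable(entries=entries)

    # long-format replicate Ki records for observed cells only
    records: list[KiRecord] = []
    for i, d in enumerate(drugs):
        for j, rec in enumerate(receptors):
            if not observed[i, j]:
                continue
            log10_ki = 9.0 - complete[i, j]
            if config.records_per_cell == 1:
                scatter = np.zeros(1)
            else:
                scatter = rng.normal(0.0, config.replicate_log10_sd, config.records_per_cell)
            for r_idx, eps in enumerate(scatter):
                records.append(
                    KiRecord(
                        drug=d,
                        receptor=rec,
                        species="human",
                        ki_nM=float(10.0 ** (log10_ki + eps)),
                        source_id=f"sim_{d}_{rec}_{r_idx}",
                    )
                )

    # clinical effects from the planted link
    effect_names, effect_kind = _effect_names(config.n_effects)
    k = len(effect_names)
    if config.effect_link == "group":
        coef = rng.normal(0.0, config.effect_scale, size=(K, k))
        signal = coef[labels]
    else:
        adj = complete - config.pki_floor
        coef = rng.normal(0.0, config.effect_scale, size=(p, k)) / np.sqrt(p)
        signal = adj @ coef
    scores = signal + rng.normal(0.0, config.effect_noise_sd, size=(n, k))
    clinical = ClinicalProfile(
        drugs=list(drugs),
        effects=effect_names,
        scores=scores,
        observed=np.ones_like(scores, dtype=bool),
        effect_kind=effect_kind,
    )

    true_scheme = GroupingScheme(
        name="true_clusters",
        assignment={d: f"cluster_{labels[i]}" for i, d in enumerate(drugs)},
    )
    shuffled = labels.copy()
    rng.shuffle(shuffled)
    random_scheme = GroupingScheme(
        name="random_grouping",
        assignment={d: f"group_{shuffled[i]}" for i, d in enumerate(drugs)},
    )

    truth = SyntheticTruth(
        partition={d: int(labels[i]) for i, d in enumerate(drugs)},
        cluster_centers=centers,
        complete_pki=complete,
        observed=observed,
        inverted_receptors=inverted,
        effect_coefficients=coef,
    )
    return SyntheticDataset(
        config=config,
        records=records,
        agonism=agonism,
        clinical=clinical,
        schemes={"true_clusters": true_scheme, "random_grouping": random_scheme},
        truth=truth,
        drugs=drugs,
        receptors=receptors,
    )


def benchmark_dataset(seed: int = 0) -> SyntheticDataset:
    """The reference-shaped benchmark: 27 drugs x 42 receptors, 4 planted
    clusters, 16 clinical effects, strong separation, 20% MCAR missingness.

    Mirrors the scale of published antipsychotic receptor-affinity datasets
    and is the workload used by the end-to-end recovery checks.
    """
    return generate(
        SyntheticConfig(
            n_drugs=27,
            n_receptors=42,
            n_clusters=4,
            separation=8.0,
            noise_sd=0.5,
            missing_rate=0.2,
            agonist_fraction=0.1,
            effect_link="group",
            effect_scale=1.0,
            effect_noise_sd=0.5,
            n_effects=16,
            records_per_cell=3,
            seed=seed,
        )
    )
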