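"""Parsing and filtering of receptor-binding records and clinical tables.

This module turns raw long-format Ki measurements (one row per published
binding study, PDSP-style) into the drug x receptor pKi affinity matrix that
every downstream analysis consumes, applying the inclusion filters of the
source protocol:

* only measurements on human tissue are kept;
* replicate (drug, receptor) measurements are collapsed by the median Ki;
* a receptor must be measured in at least 5 drugs, a drug at at least
  5 receptors;
* receptors whose Ki is identical across all drugs are dropped (they carry
  no information);
* Ki (nM) is converted to pKi = 9 - log10(Ki).

It also parses the three sidecar tables: clinical effect scores, agonism
annotations, and categorical grouping schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KiRecord",
    "AffinityMatrix",
    "ClinicalProfile",
    "AgonismTable",
    "GroupingScheme",
    "parse_ki_table",
    "filter_human",
    "ki_to_pki",
    "build_affinity_matrix",
    "parse_clinical_table",
    "parse_agonism_table",
    "parse_grouping",
]

AGONISM_MODES = ("antagonist", "agonist", "partial_agonist")


def _norm_name(name: str) -> str:
    return str(name).strip().lower()


@dataclass(frozen=True)
class KiRecord:
    """One published binding measurement.

    ``ki_nM`` is the equilibrium inhibition constant in nanomolar; lower
    values mean tighter binding.
    """

    drug: str
    receptor: str
    species: str
    ki_nM: float
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", _norm_name(self.drug))
        object.__setattr__(self, "receptor", str(self.receptor).strip().upper())
        object.__setattr__(self, "species", _norm_name(self.species))
        if not self.drug or not self.receptor:
            raise ValueError("drug and receptor must be non-empty")
        if not (self.ki_nM > 0) or not math.isfinite(self.ki_nM):
            raise ValueError(f"ki_nM must be positive and finite, got {self.ki_nM}")


@dataclass
class AffinityMatrix:
    """Drug x receptor pKi matrix with an observed-cell mask.

    Missing cells hold NaN and are False in ``observed``.
    ``provenance`` counts the input records behind each observed cell.
    """

    drugs: list[str]
    receptors: list[str]
    values: np.ndarray
    observed: np.ndarray
    provenance: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drugs, columns=self.receptors)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AffinityMatrix":
        values = frame.to_numpy(dtype=float)
        return cls(
            drugs=[str(d) for d in frame.index],
            receptors=[str(r) for r in frame.columns],
            values=values,
            observed=~np.isnan(values),
        )


@dataclass
class ClinicalProfile:
    """Drug x effect table of clinical scores (side effects + efficacy).

    The reference schema has 16 effects: 13 adverse-effect magnitudes or
    relative risks plus efficacy for total, positive and negative symptoms.
    Synthetic datasets may use any number of effects.
    """

    drugs: list[str]
    effects: list[str]
    scores: np.ndarray
    observed: np.ndarray
    effect_kind: list[str] = field(default_factory=list)  # "side_effect" | "efficacy"

    def __post_init__(self) -> None:
        if not self.effect_kind:
            self.effect_kind = ["side_effect"] * len(self.effects)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.drugs, columns=self.effects)

    def subset(self, drugs: list[str]) -> "ClinicalProfile":
        idx = [self.drugs.index(d) for d in drugs]
        return ClinicalProfile(
            drugs=list(drugs),
            effects=list(self.effects),
            scores=self.scores[idx].copy(),
            observed=self.observed[idx].copy(),
            effect_kind=list(self.effect_kind),
        )


@dataclass
class AgonismTable:
    """(drug, receptor) -> functional mode; absent pairs default to antagonist."""

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, mode in self.entries.items():
            if mode not in AGONISM_MODES:
                raise ValueError(f"unknown agonism mode {mode!r} for {key}")

    def mode(self, drug: str, receptor: str) -> str:
        return self.entries.get((_norm_name(drug), _norm_name(receptor)), "antagonist")

    def is_inverted(self, drug: str, receptor: str) -> bool:
        """True where the affinity sign is flipped (agonist or partial agonist)."""
        return self.mode(drug, receptor) in ("agonist", "partial_agonist")


@dataclass
class GroupingScheme:
    """A categorical drug classification used as a predictor set."""

    name: str
    assignment: dict[str, str]

    @property
    def n_categories(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def drugs(self) -> list[str]:
        return list(self.assignment)

    def categories(self) -> list[str]:
        return sorted(set(self.assignment.values()))


# ---------------------------------------------------------------------------
# parsing

DEFAULT_KI_COLUMNS = {
    "drug": "drug",
    "receptor": "receptor",
    "species": "species",
    "ki_nM": "ki_nM",
    "source_id": "source_id",
}


def parse_ki_table(
    path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> list[KiRecord]:
    """Read a delimited long-format Ki table into records.

    ``column_map`` maps the canonical field names (drug, receptor, species,
    ki_nM, source_id) to the file's column headers.  Rows whose Ki is missing,
    non-numeric or non-positive are dropped; the drop count is logged.
    """
    colmap = dict(DEFAULT_KI_COLUMNS)
    if column_map:
        colmap.update(column_map)
    try:
        table = pd.read_csv(path, sep=sep, engine="python")
    except OSError as exc:
        raise OSError(f"cannot read Ki table {path}: {exc}") from exc
    required = ["drug", "receptor", "species", "ki_nM"]
    missing_cols = [f for f in required if colmap[f] not in table.columns]
    if missing_cols:
        raise ValueError(
            f"Ki table {path} lacks mappable columns for {missing_cols}; "
            f"available: {list(table.columns)}"
        )
    has_source = colmap["source_id"] in table.columns

    records: list[KiRecord] = []
    n_dropped = 0
    for _, row in table.iterrows():
        ki = pd.to_numeric(row[colmap["ki_nM"]], errors="coerce")
        drug = _norm_name(row[colmap["drug"]])
        receptor = str(row[colmap["receptor"]]).strip().upper()
        if pd.isna(ki) or ki <= 0 or not drug or not receptor or receptor == "NAN":
            n_dropped += 1
            continue
        records.append(
            KiRecord(
                drug=drug,
                receptor=receptor,
                species=_norm_name(row[colmap["species"]]),
                ki_nM=float(ki),
                source_id=str(row[colmap["source_id"]]) if has_source else "",
            )
        )
    if n_dropped:
        logger.info("parse_ki_table: dropped %d invalid rows from %s", n_dropped, path)
    return records


def filter_human(records: list[KiRecord]) -> list[KiRecord]:
    """Keep only measurements on human tissue (case-insensitive match)."""
    return [r for r in records if _norm_name(r.species) == "human"]


def ki_to_pki(ki_nM: float) -> float:
    """pKi = -log10(Ki in molar) = 9 - log10(Ki in nM)."""
    if not (ki_nM > 0):
        raise ValueError(f"Ki must be positive, got {ki_nM}")
    return 9.0 - math.log10(ki_nM)


def build_affinity_matrix(
    records: list[KiRecord],
    min_drugs_per_receptor: int = 5,
    min_receptors_per_drug: int = 5,
    iterate_filters: bool = False,
) -> AffinityMatrix:
    """Aggregate records into the filtered pKi matrix.

    Steps, in order: median-collapse replicate (drug, receptor) Ki values;
    drop receptor columns observed in fewer than ``min_drugs_per_receptor``
    drugs; drop drug rows with fewer than ``min_receptors_per_drug`` remaining
    receptors; drop receptor columns constant across their observed drugs;
    convert to pKi.  The two count filters are applied once in that order by
    default; ``iterate_filters=True`` repeats them to a fixed point (removing
    a drug can push a receptor back below threshold).
    """
    if not records:
        raise ValueError("no Ki records supplied")

    frame = pd.DataFrame(
        {
            "drug": [r.drug for r in records],
            "receptor": [r.receptor for r in records],
            "ki": [r.ki_nM for r in records],
        }
    )
    ki = frame.pivot_table(index="drug", columns="receptor", values="ki", aggfunc="median")
    counts = frame.pivot_table(index="drug", columns="receptor", values="ki", aggfunc="size")
    counts = counts.reindex(index=ki.index, columns=ki.columns)

    def _apply_count_filters(mat: pd.DataFrame) -> pd.DataFrame:
        mat = mat.loc[:, mat.notna().sum(axis=0) >= min_drugs_per_receptor]
        mat = mat.loc[mat.notna().sum(axis=1) >= min_receptors_per_drug, :]
        return mat

    ki = _apply_count_filters(ki)
    if iterate_filters:
        while True:
            filtered = _apply_count_filters(ki)
            if filtered.shape == ki.shape:
                break
            ki = filtered

    # receptors with identical Ki across all observed drugs are uninformative
    def _is_constant(col: pd.Series) -> bool:
        vals = col.dropna().to_numpy()
        return vals.size > 1 and np.all(vals == vals[0])

    keep = [c for c in ki.columns if not _is_constant(ki[c])]
    ki = ki[keep]

    if ki.shape[0] == 0 or ki.shape[1] == 0:
        raise ValueError(
            "all rows or columns removed by the inclusion filters; "
            "supply more records or lower the thresholds"
        )

    pki = 9.0 - np.log10(ki.to_numpy(dtype=float))
    counts = counts.reindex(index=ki.index, columns=ki.columns)
    return AffinityMatrix(
        drugs=[str(d) for d in ki.index],
        receptors=[str(r) for r in ki.columns],
        values=pki,
        observed=~np.isnan(pki),
        provenance=np.nan_to_num(counts.to_numpy(dtype=float), nan=0.0).astype(int),
    )


DEFAULT_EFFICACY_NAMES = frozenset(
    {"efficacy_total", "efficacy_positive", "efficacy_negative"}
)


def parse_clinical_table(
    path,
    effect_kind: dict[str, str] | None = None,
    strict_schema: bool = False,
    expected_effects: list[str] | None = None,
) -> ClinicalProfile:
    """Read the drug x effect clinical score table (TSV, drugs as rows).

    ``effect_kind`` maps effect column names to "side_effect" or "efficacy";
    unlisted columns default to side_effect unless their name is one of the
    canonical efficacy columns.  ``strict_schema`` with ``expected_effects``
    rejects unknown columns.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"duplicated drug rows in clinical table: {dupes}")
    table.index = [_norm_name(d) for d in table.index]
    if strict_schema and expected_effects is not None:
        unknown = [c for c in table.columns if c not in expected_effects]
        if unknown:
            raise ValueError(f"unknown effect columns under strict schema: {unknown}")
    scores = table.to_numpy(dtype=float)
    kinds = []
    for col in table.columns:
        if effect_kind and col in effect_kind:
            kinds.append(effect_kind[col])
        elif col in DEFAULT_EFFICACY_NAMES or col.startswith("efficacy"):
            kinds.append("efficacy")
        else:
            kinds.append("side_effect")
    return ClinicalProfile(
        drugs=list(table.index),
        effects=[str(c) for c in table.columns],
        scores=scores,
        observed=~np.isnan(scores),
        effect_kind=kinds,
    )


def parse_agonism_table(path) -> AgonismTable:
    """Read a (drug, receptor, mode) TSV of agonism annotations.

    An empty file yields an empty table (all pairs default to antagonist).
    """
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return AgonismTable()
    required = {"drug", "receptor", "mode"}
    if not required.issubset(table.columns):
        raise ValueError(f"agonism table must have columns {sorted(required)}")
    entries = {}
    for _, row in table.iterrows():
        entries[(_norm_name(row["drug"]), _norm_name(row["receptor"]))] = str(
            row["mode"]
        ).strip()
    return AgonismTable(entries=entries)


def parse_grouping(path, name: str) -> GroupingScheme:
    """Read a two-column drug -> category TSV into a grouping scheme."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError("grouping table needs two columns: drug, category")
    drug_col, cat_col = table.columns[:2]
    drugs = [_norm_name(d) for d in table[drug_col]]
    if len(set(drugs)) != len(drugs):
        seen: set[str] = set()
        dupes = []
        for d in drugs:
            if d in seen:
                dupes.append(d)
            seen.add(d)
        raise ValueError(f"drug(s) listed twice in grouping table: {sorted(set(dupes))}")
    assignment = {d: str(c).strip() for d, c in zip(drugs, table[cat_col])}
    scheme = GroupingScheme(name=name, assignment=assignment)
    if scheme.n_categories == 1:
        logger.warning("grouping %r has a single category; prediction will warn", name)
    return scheme
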