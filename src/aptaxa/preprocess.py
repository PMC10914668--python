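"""Floor adjustment and agonism sign inversion of the pKi matrix.

The affinity scale is anchored so that the weakest informative binding
(pKi = 4, i.e. Ki = 100 uM) scores 0, and cells where the drug acts as an
agonist or partial agonist are negated: functionally opposite action at the
same site must not look like similarity.  Without the inversion an agonist
and an antagonist with equal affinity would be indistinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import AffinityMatrix, AgonismTable

logger = logging.getLogger(__name__)

__all__ = ["AdjustedMatrix", "floor_adjust", "apply_agonism_inversion"]

DEFAULT_FLOOR = 4.0


@dataclass
class AdjustedMatrix:
    """Floored, agonism-signed affinity matrix; the downstream fingerprint.

    Antagonist cells hold pKi - floor_constant; agonist / partial-agonist
    cells hold -(pKi - floor_constant).  The missingness mask is inherited
    unchanged from the source matrix.
    """

    drugs: list[str]
    receptors: list[str]
    values: np.ndarray
    observed: np.ndarray
    floor_constant: float = DEFAULT_FLOOR
    inverted: np.ndarray | None = None  # True where the sign was flipped

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drugs, columns=self.receptors)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="")

    def completed(self, values: np.ndarray) -> "AdjustedMatrix":
        """Return a copy with missing cells replaced by ``values``."""
        out = np.where(self.observed, self.values, values)
        return AdjustedMatrix(
            drugs=list(self.drugs),
            receptors=list(self.receptors),
            values=out,
            observed=np.ones_like(self.observed, dtype=bool),
            floor_constant=self.floor_constant,
            inverted=None if self.inverted is None else self.inverted.copy(),
        )


def floor_adjust(matrix: AffinityMatrix, floor: float = DEFAULT_FLOOR) -> AffinityMatrix:
    """Subtract the floor constant from every observed pKi.

    pKi 4 maps to 0.  Values below the floor are allowed (they go negative)
    but trigger a warning, since the reference scale assumes 4 is the minimum.
    """
    values = matrix.values.copy()
    obs = matrix.observed
    if np.any(values[obs] < floor):
        n_below = int(np.sum(values[obs] < floor))
        logger.warning("%d observed pKi values fall below the floor %g", n_below, floor)
    values[obs] = values[obs] - floor
    return AffinityMatrix(
        drugs=list(matrix.drugs),
        receptors=list(matrix.receptors),
        values=values,
        observed=obs.copy(),
        provenance=None if matrix.provenance is None else matrix.provenance.copy(),
    )


def apply_agonism_inversion(
    matrix: AffinityMatrix,
    agonism: AgonismTable,
    floor_constant: float = DEFAULT_FLOOR,
    strict: bool = False,
) -> AdjustedMatrix:
    """Negate floored affinities where the drug is an agonist or partial agonist.

    ``matrix`` must already be floor-adjusted.  Annotation entries naming a
    drug or receptor absent from the matrix are ignored with a warning, or
    rejected when ``strict``.
    """
    drug_set = {d.lower() for d in matrix.drugs}
    receptor_set = {r.lower() for r in matrix.receptors}
    unknown = [
        (d, r)
        for (d, r) in agonism.entries
        if d not in drug_set or r not in receptor_set
    ]
    if unknown:
        msg = f"{len(unknown)} agonism entries reference unknown drugs/receptors: {unknown[:5]}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)

    values = matrix.values.copy()
    inverted = np.zeros(matrix.values.shape, dtype=bool)
    for i, drug in enumerate(matrix.drugs):
        for j, receptor in enumerate(matrix.receptors):
            if agonism.is_inverted(drug, receptor):
                inverted[i, j] = True
    flip = inverted & matrix.observed
    values[flip] = -values[flip]
    return AdjustedMatrix(
        drugs=list(matrix.drugs),
        receptors=list(matrix.receptors),
        values=values,
        observed=matrix.observed.copy(),
        floor_constant=floor_constant,
        inverted=inverted,
    )
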