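"""Collaboration scores: similarity of two miRNAs (or mRNAs) through shared partners.

For miRNAs i and j with weight rows w_i, w_j over the l mRNAs,

    v_ij = (sum_k w_ik * w_jk)^2 / (sum_k w_ik * sum_k w_jk)

For a binary weight matrix this reduces to |N(i) ∩ N(j)|^2 / (|N(i)| |N(j)|),
the squared shared-target count over the product of target-set sizes, and is
bounded by 1; for general weights only non-negativity holds. The mRNA-side
matrix applies the same formula to the transposed weights. A feature with no
surviving interactions (zero row sum) scores 0 against everything, so
isolated features remain clusterable as singletons that size filters discard.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .weights import InteractionWeightMatrix


@dataclass
class CollaborationMatrix:
    """Symmetric non-negative feature-by-feature collaboration scores, zero diagonal."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        m = len(self.ids)
        if self.scores.shape != (m, m):
            raise ParameterError("collaboration matrix shape does not match ID list")
        if np.any(self.scores < 0):
            raise ParameterError("collaboration scores must be non-negative")
        if not np.allclose(self.scores, self.scores.T, atol=0, rtol=0):
            raise ParameterError("collaboration matrix must be exactly symmetric")
        if np.any(np.diagonal(self.scores) != 0):
            raise ParameterError("collaboration matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, feature_id: str) -> int:
        return self.ids.index(feature_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.ids, columns=self.ids)

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter)


def collaboration_scores(
    W: InteractionWeightMatrix, axis: str = "mirna"
) -> CollaborationMatrix:
    """Compute the miRNA-miRNA (axis="mirna") or mRNA-mRNA (axis="mrna") matrix.

    The mRNA side is the same formula on the transposed weight matrix. The
    diagonal is defined as 0 (a feature does not collaborate with itself) and
    v_ij = 0 whenever either feature's weight-row sum is 0.
    """
    if axis == "mirna":
        w = W.weights
        ids = W.mirna_ids
    elif axis == "mrna":
        w = W.weights.T
        ids = W.mrna_ids
    else:
        raise ParameterError(f"axis must be 'mirna' or 'mrna', got {axis!r}")

    inner = w @ w.T                      # inner[i, j] = sum_k w_ik w_jk
    rowsum = w.sum(axis=1)
    denom = np.outer(rowsum, rowsum)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom > 0, inner**2 / np.where(denom > 0, denom, 1.0), 0.0)
    v = (v + v.T) / 2.0                  # enforce exact symmetry against rounding
    np.fill_diagonal(v, 0.0)
    return CollaborationMatrix(ids=list(ids), scores=v)


def total_collaboration_ranking(C: CollaborationMatrix) -> list[tuple[str, float]]:
    """Features ordered by total collaboration score, descending.

    total_i = sum_k v_ik (the zero diagonal makes self-score irrelevant).
    Ties are broken by lexicographic ID order, so the ranking is stable
    across runs.
    """
    totals = C.scores.sum(axis=1)
    return sorted(zip(C.ids, totals), key=lambda kv: (-kv[1], kv[0]))
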