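"""Interaction weights: Pearson correlation of miRNA vs mRNA expression.

Each miRNA-mRNA edge of the bipartite graph is weighted by the magnitude of
the Pearson correlation coefficient (PCC) between the two expression
profiles. Using |PCC| caters for both up- and down-regulation; the
``neg_abs`` mode keeps only anti-correlated edges (|PCC| where PCC < 0),
matching the repression-only analysis variant. A magnitude cutoff eta
interpolates between fully weighted mining (eta = 0) and a sparse graph:
entries below eta are zeroed, survivors keep their |PCC| value (weighted,
never binarized).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import MatchedPair

logger = logging.getLogger(__name__)

MODES = ("abs", "neg_abs")


@dataclass
class InteractionWeightMatrix:
    """Non-negative p x q miRNA-mRNA interaction weights after the eta cutoff."""

    mirna_ids: list[str]
    mrna_ids: list[str]
    weights: np.ndarray
    eta: float
    mode: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.mirna_ids), len(self.mrna_ids)):
            raise ParameterError("weight matrix shape does not match ID lists")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ParameterError("interaction weights must lie in [0, 1]")
        nz = self.weights[self.weights > 0]
        if nz.size and nz.min() < self.eta - 1e-12:
            raise ParameterError("nonzero weight below the stored eta cutoff")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.mirna_ids, columns=self.mrna_ids)

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter)


def _pearson_cross(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cross-correlation matrix between the rows of x (p x n) and y (q x n).

    Rows with zero variance get correlation 0 (PCC undefined), with a warning.
    The n-1 covariance divisor cancels in the PCC ratio.
    """
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum(axis=1))
    zero_x = sx <= 0
    zero_y = sy <= 0
    if zero_x.any() or zero_y.any():
        warnings.warn(
            f"{int(zero_x.sum())} miRNA and {int(zero_y.sum())} mRNA features have "
            "zero variance; their interaction weights are set to 0",
            stacklevel=3,
        )
    sx = np.where(zero_x, 1.0, sx)
    sy = np.where(zero_y, 1.0, sy)
    r = (xc @ yc.T) / np.outer(sx, sy)
    r[zero_x, :] = 0.0
    r[:, zero_y] = 0.0
    # guard against rounding outside [-1, 1]
    return np.clip(r, -1.0, 1.0)


def pearson_weights(pair: MatchedPair, mode: str = "abs") -> np.ndarray:
    """Raw (pre-cutoff) p x q weight matrix from an aligned expression pair.

    mode="abs": entry_ij = |PCC(miRNA_i, mRNA_j)|.
    mode="neg_abs": |PCC| where PCC < 0, else 0 (anti-correlated edges only).
    """
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    r = _pearson_cross(pair.mirna.values, pair.mrna.values)
    if mode == "abs":
        return np.abs(r)
    return np.where(r < 0, -r, 0.0)


def apply_cutoff(
    raw: np.ndarray,
    eta: float,
    mirna_ids: list[str],
    mrna_ids: list[str],
    mode: str = "abs",
) -> InteractionWeightMatrix:
    """Zero out entries below eta; survivors keep their weight.

    eta = 0 leaves the matrix unchanged; eta = 1 keeps only exact-1 entries.
    """
    if not 0.0 <= eta <= 1.0:
        raise ParameterError(f"eta must be in [0, 1], got {eta}")
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0) or np.any(raw > 1):
        raise ParameterError("raw weights must lie in [0, 1]")
    cut = np.where(raw >= eta, raw, 0.0)
    logger.debug(
        "eta=%.2f keeps %d of %d edges", eta, int((cut > 0).sum()), cut.size
    )
    return InteractionWeightMatrix(
        mirna_ids=list(mirna_ids), mrna_ids=list(mrna_ids),
        weights=cut, eta=eta, mode=mode,
    )


def interaction_weights(
    pair: MatchedPair, eta: float, mode: str = "abs"
) -> InteractionWeightMatrix:
    """Convenience: pearson_weights followed by apply_cutoff."""
    raw = pearson_weights(pair, mode=mode)
    return apply_cutoff(raw, eta, pair.mirna.feature_ids, pair.mrna.feature_ids, mode)


def weights_from_file(
    path: str | Path, eta: float, mode: str = "precomputed", delimiter: str = "\t"
) -> InteractionWeightMatrix:
    """Load a precomputed [0,1] weight matrix (miRNA rows, mRNA columns) and cut at eta.

    Keeps the door open for weight sources other than PCC (e.g. MIC, Lasso).
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    return apply_cutoff(
        frame.to_numpy(dtype=float), eta,
        [str(i) for i in frame.index], [str(c) for c in frame.columns], mode,
    )
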