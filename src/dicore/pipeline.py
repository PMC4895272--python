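"""End-to-end module discovery: estimator, sweep orchestration, validation.

:class:`DICORE` is a scikit-learn-style estimator: construct with
hyperparameters, call :meth:`DICORE.fit` with the matched miRNA and mRNA
expression matrices (features x samples), then read the fitted attributes
(``weights_``, ``mirna_groups_``, ``mrna_groups_``, ``cores_``,
``summary_``). :func:`run_dicore` sweeps the eta cutoff over a grid,
writing per-eta artifacts and a concatenated summary table.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cca import CORE, score_group_pairs
from .collaboration import collaboration_scores
from .exceptions import ParameterError
from .grouping import Group, GroupingParams, discover_groups, groups_to_json
from .io import ExpressionMatrix, InteractionReference, MatchedPair, align_samples
from .weights import interaction_weights

logger = logging.getLogger(__name__)


@dataclass
class SummaryRow:
    """Per-eta summary: CORE count and mean sizes/strength over emitted COREs."""

    eta: float
    n_cores: int
    mean_mrnas: float
    mean_mirnas: float
    mean_strength: float

    def to_json(self) -> dict:
        return {
            "eta": self.eta,
            "n_cores": self.n_cores,
            "mean_mrnas": self.mean_mrnas,
            "mean_mirnas": self.mean_mirnas,
            "mean_strength": self.mean_strength,
        }

    def to_tsv_fields(self) -> list[str]:
        return [
            f"{self.eta:.2f}",
            str(self.n_cores),
            f"{self.mean_mrnas:.2f}",
            f"{self.mean_mirnas:.2f}",
            f"{self.mean_strength:.2f}",
        ]


def summarize(cores: list[CORE], eta: float) -> SummaryRow | None:
    """Arithmetic means of mRNA count, miRNA count and r over the CORE list.

    Returns None (the no-row signal) for an empty list; summary tables omit
    such rows.
    """
    if not cores:
        return None
    return SummaryRow(
        eta=eta,
        n_cores=len(cores),
        mean_mrnas=float(np.mean([len(c.mrna_group) for c in cores])),
        mean_mirnas=float(np.mean([len(c.mirna_group) for c in cores])),
        mean_strength=float(np.mean([c.strength for c in cores])),
    )


def count_confirmed(
    core: CORE, ref: InteractionReference
) -> tuple[int, dict[str, list[str]]]:
    """Count reference-confirmed interactions inside one CORE.

    Returns the count and the confirmed mRNAs grouped per miRNA (sorted),
    mirroring the per-miRNA listing layout of validation tables.
    """
    by_mirna: dict[str, list[str]] = {}
    total = 0
    for m in core.mirna_group.sorted_members():
        hits = [g for g in core.mrna_group.sorted_members() if (m, g) in ref]
        if hits:
            by_mirna[m] = hits
            total += len(hits)
    return total, by_mirna


class DICORE(BaseEstimator):
    """Discover miRNA-mRNA regulatory modules as collective group relationships.

    Parameters
    ----------
    eta : float, default=0.5
        Magnitude cutoff on |PCC| interaction weights; 0 keeps the complete
        weighted bipartite graph, larger values sparsify it.
    weights_mode : {"abs", "neg_abs"}, default="abs"
        "abs" keeps |PCC| for every edge; "neg_abs" keeps only
        anti-correlated edges (repression-only variant).
    alpha : float, default=2.0
        Cohesiveness penalty per group member (assumed undetected
        interactions).
    min_mirnas, min_mrnas : int
        Minimum group sizes (theta_m = 3 avoids star structures;
        theta_g = 5 drops uninformative mRNA groups).
    max_mirnas, max_mrnas : int or None
        Maximum group sizes; by default only mRNA groups are capped (500).
    merge_overlap : float, default=0.8
        Overlap-score threshold omega for merging redundant groups.
    min_density : float or None, default=None
        Optional density floor on groups.
    rho : float, default=0.5
        Minimum first canonical correlation for a group pair to be a CORE.
    cca_method : {"sparse_pmd", "ridge_regularized", "classical"}
        Solver for group-pair strength; sparse_pmd handles groups larger
        than the sample count.
    cca_penalty_x, cca_penalty_y : float, default=0.3
        l1 penalty fractions for the sparse solver.

    Attributes
    ----------
    weights_ : InteractionWeightMatrix
    collab_mirna_, collab_mrna_ : CollaborationMatrix
    mirna_groups_, mrna_groups_ : list of Group
    cores_ : list of CORE
    summary_ : SummaryRow or None
    """

    def __init__(
        self,
        eta: float = 0.5,
        weights_mode: str = "abs",
        alpha: float = 2.0,
        min_mirnas: int = 3,
        min_mrnas: int = 5,
        max_mirnas: int | None = None,
        max_mrnas: int | None = 500,
        merge_overlap: float = 0.8,
        min_density: float | None = None,
        rho: float = 0.5,
        cca_method: str = "sparse_pmd",
        cca_penalty_x: float = 0.3,
        cca_penalty_y: float = 0.3,
    ):
        self.eta = eta
        self.weights_mode = weights_mode
        self.alpha = alpha
        self.min_mirnas = min_mirnas
        self.min_mrnas = min_mrnas
        self.max_mirnas = max_mirnas
        self.max_mrnas = max_mrnas
        self.merge_overlap = merge_overlap
        self.min_density = min_density
        self.rho = rho
        self.cca_method = cca_method
        self.cca_penalty_x = cca_penalty_x
        self.cca_penalty_y = cca_penalty_y

    # -- helpers -----------------------------------------------------------
    def _grouping_params(self, side: str) -> GroupingParams:
        if side == "mirna":
            mx = math.inf if self.max_mirnas is None else self.max_mirnas
            return GroupingParams(
                alpha=self.alpha, min_size=self.min_mirnas, max_size=mx,
                merge_overlap=self.merge_overlap, min_density=self.min_density,
            )
        mx = math.inf if self.max_mrnas is None else self.max_mrnas
        return GroupingParams(
            alpha=self.alpha, min_size=self.min_mrnas, max_size=mx,
            merge_overlap=self.merge_overlap, min_density=self.min_density,
        )

    @staticmethod
    def _as_pair(X, Y) -> MatchedPair:
        if isinstance(X, MatchedPair):
            return X
        if isinstance(X, pd.DataFrame):
            X = ExpressionMatrix.from_frame(X)
        if isinstance(Y, pd.DataFrame):
            Y = ExpressionMatrix.from_frame(Y)
        if not isinstance(X, ExpressionMatrix) or not isinstance(Y, ExpressionMatrix):
            raise ParameterError(
                "fit expects ExpressionMatrix or DataFrame inputs "
                "(features x samples) for both views"
            )
        return align_samples(X, Y)

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, Y=None):
        """Run the full pipeline on matched miRNA (X) and mRNA (Y) expression.

        X may also be a pre-aligned :class:`MatchedPair` (with Y omitted).
        Returns self, with fitted attributes populated.
        """
        pair = self._as_pair(X, Y)
        self.pair_ = pair
        self.weights_ = interaction_weights(pair, self.eta, mode=self.weights_mode)
        self.collab_mirna_ = collaboration_scores(self.weights_, axis="mirna")
        self.collab_mrna_ = collaboration_scores(self.weights_, axis="mrna")
        self.mirna_groups_ = discover_groups(
            self.collab_mirna_, self._grouping_params("mirna"), side="mirna"
        )
        self.mrna_groups_ = discover_groups(
            self.collab_mrna_, self._grouping_params("mrna"), side="mrna"
        )
        cca_kwargs = {}
        if self.cca_method == "sparse_pmd":
            cca_kwargs = {
                "penalty_x": self.cca_penalty_x,
                "penalty_y": self.cca_penalty_y,
            }
        self.cores_ = score_group_pairs(
            self.mirna_groups_, self.mrna_groups_, pair,
            rho=self.rho, method=self.cca_method, **cca_kwargs,
        )
        self.summary_ = summarize(self.cores_, self.eta)
        return self

    def fit_predict(self, X, Y=None) -> list[CORE]:
        return self.fit(X, Y).cores_


@dataclass
class RunConfig:
    """Configuration for a (possibly multi-eta) pipeline run."""

    etas: list[float] = field(default_factory=lambda: [round(0.05 * k, 2) for k in range(21)])
    weights_mode: str = "abs"
    alpha: float = 2.0
    min_mirnas: int = 3
    min_mrnas: int = 5
    max_mirnas: int | None = None
    max_mrnas: int | None = 500
    merge_overlap: float = 0.8
    min_density: float | None = None
    rho: float = 0.5
    cca_method: str = "sparse_pmd"
    cca_penalty_x: float = 0.3
    cca_penalty_y: float = 0.3
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not self.etas:
            raise ParameterError("eta list must be nonempty")
        for e in self.etas:
            if not 0.0 <= e <= 1.0:
                raise ParameterError(f"eta {e} outside [0, 1]")

    def estimator(self, eta: float) -> DICORE:
        return DICORE(
            eta=eta, weights_mode=self.weights_mode, alpha=self.alpha,
            min_mirnas=self.min_mirnas, min_mrnas=self.min_mrnas,
            max_mirnas=self.max_mirnas, max_mrnas=self.max_mrnas,
            merge_overlap=self.merge_overlap, min_density=self.min_density,
            rho=self.rho, cca_method=self.cca_method,
            cca_penalty_x=self.cca_penalty_x, cca_penalty_y=self.cca_penalty_y,
        )


@dataclass
class EtaResult:
    """Artifacts of one eta value within a sweep."""

    eta: float
    mirna_groups: list[Group]
    mrna_groups: list[Group]
    cores: list[CORE]
    summary: SummaryRow | None


SUMMARY_COLUMNS = ["eta", "n_cores", "mean_mrnas", "mean_mirnas", "mean_strength"]


def run_dicore(
    config: RunConfig,
    pair: MatchedPair,
    reference: InteractionReference | None = None,
) -> list[EtaResult]:
    """Run the pipeline for each eta in the config; optionally write artifacts.

    When ``config.out_dir`` is set, each eta gets its own subdirectory with
    ``groups.json`` and ``cores.json`` (and ``confirmed.tsv`` when a
    reference is supplied), plus a top-level ``summary.tsv`` concatenating
    the non-empty summary rows. Fully deterministic: identical inputs give
    byte-identical outputs.
    """
    results: list[EtaResult] = []
    for eta in config.etas:
        try:
            est = config.estimator(eta).fit(pair)
        except Exception as exc:
            raise type(exc)(f"eta={eta}: {exc}") from exc
        res = EtaResult(
            eta=eta,
            mirna_groups=est.mirna_groups_,
            mrna_groups=est.mrna_groups_,
            cores=est.cores_,
            summary=est.summary_,
        )
        results.append(res)
        if config.out_dir is not None:
            _write_eta_artifacts(Path(config.out_dir), res, reference)
    if config.out_dir is not None:
        _write_summary(Path(config.out_dir), results)
    return results


def _write_eta_artifacts(
    out_dir: Path, res: EtaResult, reference: InteractionReference | None
) -> None:
    sub = out_dir / f"eta_{res.eta:.2f}"
    sub.mkdir(parents=True, exist_ok=True)
    with open(sub / "groups.json", "w") as fh:
        json.dump(
            {
                "mirna_groups": groups_to_json(res.mirna_groups),
                "mrna_groups": groups_to_json(res.mrna_groups),
            },
            fh, indent=2, sort_keys=True,
        )
    with open(sub / "cores.json", "w") as fh:
        json.dump([c.to_json() for c in res.cores], fh, indent=2, sort_keys=True)
    _write_cores_tsv(sub / "cores.tsv", res.cores)
    if reference is not None:
        _write_confirmed(sub / "confirmed.tsv", res.cores, reference)


def _write_cores_tsv(path: Path, cores: list[CORE]) -> None:
    with open(path, "w") as fh:
        fh.write("core_id\tr\tn_mirnas\tn_mrnas\tmembers\n")
        for c in cores:
            members = ",".join(c.mirna_group.sorted_members()
                               + c.mrna_group.sorted_members())
            fh.write(
                f"C{c.rank}\t{c.strength:.4f}\t{len(c.mirna_group)}"
                f"\t{len(c.mrna_group)}\t{members}\n"
            )


def _write_confirmed(path: Path, cores: list[CORE],
                     reference: InteractionReference) -> None:
    with open(path, "w") as fh:
        fh.write("core_id\tn_confirmed\tmirna\tconfirmed_mrnas\n")
        for c in cores:
            n, by_mirna = count_confirmed(c, reference)
            if not by_mirna:
                fh.write(f"C{c.rank}\t0\t\t\n")
                continue
            for m, hits in by_mirna.items():
                fh.write(f"C{c.rank}\t{n}\t{m}\t{','.join(hits)}\n")


def _write_summary(out_dir: Path, results: list[EtaResult]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [r.summary for r in results if r.summary is not None]
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row.to_tsv_fields()) + "\n")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump([r.to_json() for r in rows], fh, indent=2, sort_keys=True)
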