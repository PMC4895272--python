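"""Reading, validation and alignment of matched expression matrices.

Expression tables are delimited text with sample IDs in the header row and
feature IDs in the first column; the body is strictly numeric. Matrices are
oriented features x samples (each feature is a variable observed over the
matched samples). Orientation is declared by the caller, never guessed:
silent transposition is a classic silent-corruption bug, so a table that
looks transposed is still read as given.

Missing values are rejected rather than imputed: inputs are assumed to be
fully pre-processed (e.g. differentially expressed, normalised) upstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateIDError,
    InsufficientOverlapError,
    MissingFileError,
    NonNumericError,
    RaggedRowError,
    ReferenceParseError,
)

logger = logging.getLogger(__name__)

# tokens that mark the first line of a reference table as a header
_HEADER_TOKENS = {
    "mirna", "mirna_id", "mir", "mir_id", "microrna", "source", "from",
    "mrna", "mrna_id", "gene", "gene_id", "target", "to",
}


@dataclass
class ExpressionMatrix:
    """A feature-by-sample real-valued expression matrix with string IDs.

    Parameters
    ----------
    feature_ids : list of str
        Unique row labels (miRNA or mRNA identifiers).
    sample_ids : list of str
        Unique column labels.
    values : ndarray of shape (n_features, n_samples)
        Finite expression levels (log-scale assumed, unitless).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise NonNumericError("expression values must form a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise NonNumericError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise DuplicateIDError(f"duplicate {kind} IDs: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise NonNumericError("expression matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, ids: list[str]) -> np.ndarray:
        """Return the value rows for `ids`, in the given order."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        return self.values[[pos[i] for i in ids], :]

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter)


@dataclass
class MatchedPair:
    """Matched miRNA and mRNA expression over an identical ordered sample set."""

    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    dropped_mirna_samples: list[str] = field(default_factory=list)
    dropped_mrna_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mirna.sample_ids != self.mrna.sample_ids:
            raise InsufficientOverlapError(
                "matched pair requires identical sample IDs in identical order; "
                "use align_samples() first"
            )
        if self.mirna.n_samples < 3:
            raise InsufficientOverlapError(
                f"need >= 3 matched samples for correlation, got {self.mirna.n_samples}"
            )

    @property
    def n_samples(self) -> int:
        return self.mirna.n_samples


@dataclass(frozen=True)
class InteractionReference:
    """A deduplicated set of (miRNA_id, mRNA_id) confirmed-interaction pairs."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            for m, g in sorted(self.pairs):
                fh.write(f"{m}{delimiter}{g}\n")


def read_expression(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited expression table into a validated :class:`ExpressionMatrix`.

    First row = sample IDs, first column = feature IDs, numeric body.
    Duplicate IDs, non-numeric cells (including NA markers) and ragged rows
    each raise a distinct error; nothing is imputed.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"expression file not found: {path}")
    try:
        frame = pd.read_csv(
            path, sep=delimiter, index_col=0, header=0, dtype=str,
            keep_default_na=False, na_filter=False,
        )
    except pd.errors.ParserError as exc:
        raise RaggedRowError(f"ragged rows in {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise DuplicateIDError(f"duplicate feature IDs in {path}: {dupes}")
    ncols = frame.shape[1]
    # pandas pads short rows with empty fields; surface those as ragged
    empty = frame.isna() | (frame == "")
    if empty.any(axis=None):
        bad = frame.index[empty.any(axis=1)].tolist()
        raise RaggedRowError(f"rows with missing fields in {path}: {bad[:5]}")
    try:
        values = frame.astype(float)
    except ValueError as exc:
        raise NonNumericError(f"non-numeric cell in {path}: {exc}") from exc
    if values.isna().any(axis=None) or not np.isfinite(values.to_numpy()).all():
        raise NonNumericError(f"missing or non-finite expression values in {path}")
    logger.info("read %d features x %d samples from %s", len(frame), ncols, path)
    return ExpressionMatrix.from_frame(values)


def align_samples(mirna: ExpressionMatrix, mrna: ExpressionMatrix) -> MatchedPair:
    """Restrict both matrices to their common samples, identically ordered.

    Sample matching is by exact string equality. The common samples keep the
    order they have in the miRNA matrix (a single canonical order for both
    members). Raises :class:`InsufficientOverlapError` for < 3 shared IDs.
    """
    common = set(mirna.sample_ids) & set(mrna.sample_ids)
    if len(common) < 3:
        raise InsufficientOverlapError(
            f"only {len(common)} common samples between matrices; need >= 3"
        )
    order = [s for s in mirna.sample_ids if s in common]
    dropped_mi = [s for s in mirna.sample_ids if s not in common]
    dropped_mr = [s for s in mrna.sample_ids if s not in common]
    if dropped_mi or dropped_mr:
        logger.info(
            "align_samples dropped %d miRNA and %d mRNA samples",
            len(dropped_mi), len(dropped_mr),
        )

    def _restrict(m: ExpressionMatrix) -> ExpressionMatrix:
        pos = {s: j for j, s in enumerate(m.sample_ids)}
        cols = [pos[s] for s in order]
        return ExpressionMatrix(m.feature_ids, order, m.values[:, cols])

    return MatchedPair(
        mirna=_restrict(mirna),
        mrna=_restrict(mrna),
        dropped_mirna_samples=dropped_mi,
        dropped_mrna_samples=dropped_mr,
    )


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def read_reference(path: str | Path, delimiter: str = "\t") -> InteractionReference:
    """Read a two-column (miRNA, mRNA) interaction table or its JSON form.

    An optional single header line is detected by a non-ID first token.
    Duplicate pairs are collapsed silently with a logged count; a line with
    other than two columns raises :class:`ReferenceParseError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"reference file not found: {path}")
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        return _reference_from_json(stripped, path)
    pairs: list[tuple[str, str]] = []
    lines = text.splitlines()
    start = 0
    if lines:
        first = lines[0].split(delimiter)
        if len(first) == 2 and _looks_like_header(first):
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        if len(fields) != 2:
            raise ReferenceParseError(
                f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
            )
        pairs.append((fields[0].strip(), fields[1].strip()))
    unique = frozenset(pairs)
    if len(unique) < len(pairs):
        logger.info("collapsed %d duplicate reference pairs", len(pairs) - len(unique))
    return InteractionReference(pairs=unique)


def _reference_from_json(text: str, path: Path) -> InteractionReference:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ReferenceParseError(f"{path}: invalid JSON reference: {exc}") from exc
    if isinstance(payload, dict) and "pairs" in payload:
        payload = payload["pairs"]
    if not isinstance(payload, list):
        raise ReferenceParseError(f"{path}: JSON reference must be a list of pairs")
    pairs = set()
    for i, entry in enumerate(payload):
        if not isinstance(entry, (list, tuple)) or len(entry) != 2:
            raise ReferenceParseError(f"{path}: entry {i} is not a 2-item pair")
        pairs.add((str(entry[0]), str(entry[1])))
    return InteractionReference(pairs=frozenset(pairs))
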