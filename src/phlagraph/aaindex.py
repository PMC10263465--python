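"""Amino-acid featurization from AAindex1-format physicochemical indices.

Each AAindex1 record assigns one real number to each of the 20 standard
amino acids (e.g. hydrophobicity, volume, alpha-helix propensity).  This
module turns a file of such indices into a dense per-residue embedding:

1. parse the flat-file records (``H``/``D``/``I`` blocks, ``//`` terminators,
   ``NA`` for missing values),
2. drop every index with at least one missing value,
3. robust-scale each retained index over the 20 residues
   (``(x - median) / IQR``),
4. run PCA on the resulting 20 x F matrix and keep the scores of the top
   ``n_components`` (default 20) components as the residue embedding.

Because a column-centered matrix with 20 rows has rank at most 19, the last
of 20 requested components carries (numerically) zero variance; this is
expected and logged rather than treated as an error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: The 20 standard residues in fixed alphabetical one-letter order.  This is
#: the row order of every matrix in this module.
RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: One-letter codes that are legal in sequences but have no physicochemical
#: row: ambiguity codes and the rare translated residues.
NONSTANDARD_RESIDUES: frozenset[str] = frozenset("BJOUXZ")


class AAindexParseError(ValueError):
    """Raised when an AAindex1 stream cannot be parsed."""


@dataclass
class IndexRecord:
    """One AAindex1 record: an accession, a title and 20 residue values."""

    accession: str
    title: str
    values: dict[str, float | None]

    @property
    def has_missing(self) -> bool:
        return any(v is None for v in self.values.values())


@dataclass
class RawIndexTable:
    """All records parsed from one AAindex1 file, in file order."""

    records: list[IndexRecord]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CompleteIndexMatrix:
    """20 x F matrix of complete indices; rows follow :data:`RESIDUES`."""

    matrix: np.ndarray  # (20, F)
    column_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (20, len(self.column_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.column_ids)} column ids"
            )

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class AminoAcidFeatureTable:
    """Per-residue embedding plus the PCA/normalization metadata behind it."""

    embedding: dict[str, np.ndarray]  # residue -> (n_components,)
    component_loadings: np.ndarray  # (F, n_components), orthonormal columns
    explained_variance: np.ndarray  # (n_components,), non-increasing
    column_ids: list[str]
    medians: np.ndarray  # per retained column, pre-normalization
    iqrs: np.ndarray

    @property
    def n_components(self) -> int:
        return self.component_loadings.shape[1]

    def vector(self, residue: str) -> np.ndarray:
        vec, _ = embed_residue(residue, self)
        return vec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.embedding[r] for r in RESIDUES],
            index=list(RESIDUES),
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )

    def save(self, outdir: str | Path) -> None:
        """Write the embedding as TSV plus a JSON metadata sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        frame.to_csv(outdir / "embedding.tsv", sep="\t", index_label="residue")
        meta = {
            "column_ids": self.column_ids,
            "explained_variance": self.explained_variance.tolist(),
            "medians": self.medians.tolist(),
            "iqrs": self.iqrs.tolist(),
            "component_loadings": self.component_loadings.tolist(),
        }
        (outdir / "embedding_meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, outdir: str | Path) -> "AminoAcidFeatureTable":
        outdir = Path(outdir)
        frame = pd.read_csv(outdir / "embedding.tsv", sep="\t", index_col="residue")
        meta = json.loads((outdir / "embedding_meta.json").read_text())
        embedding = {r: frame.loc[r].to_numpy(dtype=float) for r in RESIDUES}
        return cls(
            embedding=embedding,
            component_loadings=np.asarray(meta["component_loadings"], dtype=float),
            explained_variance=np.asarray(meta["explained_variance"], dtype=float),
            column_ids=list(meta["column_ids"]),
            medians=np.asarray(meta["medians"], dtype=float),
            iqrs=np.asarray(meta["iqrs"], dtype=float),
        )


def _parse_value(token: str) -> float | None:
    if token.upper() == "NA":
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise AAindexParseError(f"unparsable value {token!r}") from exc


def parse_aaindex(stream: TextIO | str | Path) -> RawIndexTable:
    """Parse an AAindex1 flat-format stream into a :class:`RawIndexTable`.

    The ``I`` line carries ten ``X/Y`` residue-pair headers; the first data
    line below it holds the values for the ``X`` residues and the second the
    values for the ``Y`` residues.  ``NA`` marks a missing value.

    Raises
    ------
    AAindexParseError
        For an empty stream, a record without an accession, or an ``I``
        block that does not resolve to exactly 20 residue values.
    """
    if isinstance(stream, (str, Path)):
        text = Path(stream).read_text()
    else:
        text = stream.read()
    if not text.strip():
        raise AAindexParseError("empty AAindex stream")

    records: list[IndexRecord] = []
    seen: set[str] = set()
    for chunk in text.split("\n//"):
        if not chunk.strip():
            continue
        lines = chunk.splitlines()
        accession = ""
        title = ""
        i_header: list[str] | None = None
        data_tokens: list[str] = []
        in_i_block = False
        for line in lines:
            if line.startswith("H "):
                accession = line[2:].strip()
                in_i_block = False
            elif line.startswith("D "):
                title = line[2:].strip()
                in_i_block = False
            elif line.startswith("I "):
                i_header = line[2:].split()
                in_i_block = True
            elif in_i_block and (line.startswith(" ") or line.startswith("\t")):
                data_tokens.extend(line.split())
            elif line[:1].isalpha():
                in_i_block = False
        if not accession:
            raise AAindexParseError("record without H (accession) line")
        if accession in seen:
            raise AAindexParseError(f"duplicate accession {accession}")
        seen.add(accession)
        if i_header is None or len(i_header) != 10 or len(data_tokens) != 20:
            raise AAindexParseError(
                f"record {accession}: I-block does not contain 20 values "
                f"(got {len(data_tokens)})"
            )
        firsts = [h.split("/")[0] for h in i_header]
        seconds = [h.split("/")[1] for h in i_header]
        order = firsts + seconds
        if sorted(order) != sorted(RESIDUES):
            raise AAindexParseError(
                f"record {accession}: I-block residues are not the 20 standard"
            )
        values = {res: _parse_value(tok) for res, tok in zip(order, data_tokens)}
        records.append(IndexRecord(accession=accession, title=title, values=values))
    if not records:
        raise AAindexParseError("no records found in AAindex stream")
    return RawIndexTable(records=records)


def drop_missing(raw: RawIndexTable) -> CompleteIndexMatrix:
    """Drop every index with a missing value; keep file column order."""
    kept = [rec for rec in raw.records if not rec.has_missing]
    if not kept:
        raise ValueError("no complete indices remain after missing-value removal")
    matrix = np.array(
        [[rec.values[res] for rec in kept] for res in RESIDUES], dtype=float
    )
    return CompleteIndexMatrix(matrix=matrix, column_ids=[r.accession for r in kept])


def robust_normalize(matrix: CompleteIndexMatrix) -> CompleteIndexMatrix:
    """Scale each column to ``(x - median) / IQR`` over the 20 residues.

    Quartiles use linear interpolation.  Columns with zero IQR carry no
    rank information at this resolution and are dropped with a warning.
    """
    X = matrix.matrix
    med = np.median(X, axis=0)
    q1, q3 = np.percentile(X, [25, 75], axis=0)
    iqr = q3 - q1
    keep = iqr > 0
    if not keep.any():
        raise ValueError("all columns are constant (zero IQR); nothing to normalize")
    dropped = [cid for cid, k in zip(matrix.column_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d zero-IQR column(s): %s", len(dropped), dropped)
    Xn = (X[:, keep] - med[keep]) / iqr[keep]
    return CompleteIndexMatrix(
        matrix=Xn, column_ids=[c for c, k in zip(matrix.column_ids, keep) if k]
    )


def _fix_component_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip each component so its largest-magnitude loading entry is positive.

    PCA is defined only up to a per-component sign; pinning it makes the
    embedding bitwise reproducible across runs and platforms.  Operates
    in place on ``loadings`` (F x C) and ``scores`` (20 x C).
    """
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            loadings[:, c] = -col
            scores[:, c] = -scores[:, c]


def fit_pca_embedding(
    matrix: CompleteIndexMatrix, n_components: int = 20
) -> AminoAcidFeatureTable:
    """PCA on the robust-normalized 20 x F index matrix.

    The 20 residues are the observations and the F indices the variables;
    the residue embedding is the matrix of PCA scores for the leading
    ``n_components`` components.
    """
    if matrix.n_features < n_components:
        raise ValueError(
            f"need at least {n_components} columns for {n_components} components, "
            f"got {matrix.n_features}"
        )
    X = matrix.matrix
    med = np.median(X, axis=0)
    q1, q3 = np.percentile(X, [25, 75], axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # (F, C)
    _fix_component_signs(loadings, scores)
    # Recompute scores from the sign-fixed loadings for exact consistency.
    scores = (X - X.mean(axis=0)) @ loadings
    variances = pca.explained_variance_.copy()
    if n_components >= min(X.shape):
        ratio = variances[-1] / max(variances[0], np.finfo(float).tiny)
        logger.info(
            "last component variance ratio %.3e (rank-deficient input, expected)",
            ratio,
        )
    embedding = {res: scores[i].copy() for i, res in enumerate(RESIDUES)}
    return AminoAcidFeatureTable(
        embedding=embedding,
        component_loadings=loadings,
        explained_variance=variances,
        column_ids=list(matrix.column_ids),
        medians=med,
        iqrs=q3 - q1,
    )


def embed_residue(
    residue: str, table: AminoAcidFeatureTable
) -> tuple[np.ndarray, bool]:
    """Return ``(vector, nonstandard_flag)`` for a one-letter residue code.

    Standard residues return their embedding row.  Nonstandard but legal
    codes (B, J, O, U, X, Z) return the zero vector with the flag set, so
    curated datasets containing rare codes degrade gracefully instead of
    aborting.  Lowercase input is accepted and upper-cased.
    """
    if not isinstance(residue, str) or len(residue) != 1 or not residue.isalpha():
        raise ValueError(f"not a one-letter residue code: {residue!r}")
    res = residue.upper()
    if res in table.embedding:
        return table.embedding[res].copy(), False
    if res in NONSTANDARD_RESIDUES:
        return np.zeros(table.n_components), True
    raise ValueError(f"unknown residue code: {residue!r}")


def build_embedding(
    aaindex_path: str | Path, n_components: int = 20
) -> AminoAcidFeatureTable:
    """Convenience pipeline: parse -> drop missing -> normalize -> PCA."""
    raw = parse_aaindex(aaindex_path)
    return fit_pca_embedding(
        robust_normalize(drop_missing(raw)), n_components=n_components
    )
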