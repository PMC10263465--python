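"""Curation of T-cell assay records into a labeled training set.

Immunogenicity assay exports (IEDB-style tables of peptide, HLA restriction,
assay type and outcome counts) are noisy: alleles may be reported at
serotype resolution only, counts may be missing, and the same peptide-HLA
pair may appear with conflicting outcomes.  ``filter_records`` applies a
fixed cleaning cascade:

1. drop records whose HLA allele lacks 4-digit resolution (and, by default,
   records that are not MHC class I);
2. drop records missing the count fields their outcome requires;
3. keep negatives only when at least ``min_negative_experiments`` (default 4)
   experiments were performed, all negative;
4. keep positives only when at least one tested subject responded;
5. collapse duplicate (peptide, allele) instances — concordant duplicates
   merge into one instance, discordant ones are discarded by default
   (configurable to majority vote or positive-wins).

The module also provides the database similarity search used to compare a
query peptide against a collection of validated epitopes: global pairwise
alignment under BLOSUM62 (gap open 11, extend 1), with the score normalized
by the geometric mean of the two self-alignment scores so that identity
scores exactly 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .graph import AlleleError, normalize_allele

logger = logging.getLogger(__name__)

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Maps common IEDB-export column headers onto our canonical field names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "Description": "peptide",
    "Epitope": "peptide",
    "Allele Name": "allele",
    "MHC Allele": "allele",
    "Assay Group": "assay_class",
    "Qualitative Measure": "qualitative_outcome",
    "Number of Subjects Tested": "n_subjects_tested",
    "Number of Subjects Responded": "n_subjects_responded",
    "Number of Experiments": "n_experiments",
    "Host": "host",
    "MHC Class": "mhc_class",
}


@dataclass
class AssayRecord:
    """One assay measurement of a peptide-HLA pair."""

    peptide: str
    allele: str
    qualitative_outcome: str  # "positive" | "negative"
    assay_class: str = "other"  # cytokine release / cytotoxicity / other
    n_experiments: int | None = None
    n_subjects_tested: int | None = None
    n_subjects_responded: int | None = None
    host: str = "Homo sapiens"
    mhc_class: str = "I"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.qualitative_outcome = self.qualitative_outcome.strip().lower()
        for f in ("n_experiments", "n_subjects_tested", "n_subjects_responded"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise ValueError(f"{f} must be non-negative, got {v}")


@dataclass
class Instance:
    """One deduplicated labeled peptide-HLA training instance."""

    peptide: str
    allele: str
    label: int
    sources: tuple[str, ...] = ()


@dataclass
class CuratedDataset:
    """Labeled, deduplicated peptide-HLA instances with record provenance."""

    instances: list[Instance]

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def labels(self) -> list[int]:
        return [i.label for i in self.instances]

    def class_counts(self) -> tuple[int, int]:
        pos = sum(i.label for i in self.instances)
        return pos, len(self.instances) - pos

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.peptide, i.allele, i.label) for i in self.instances],
            columns=["peptide", "allele", "label"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CuratedDataset":
        df = pd.read_csv(path, sep="\t")
        return cls(
            instances=[
                Instance(str(r.peptide), str(r.allele), int(r.label))
                for r in df.itertuples()
            ]
        )


@dataclass
class CurationPolicy:
    """Tunable thresholds and tie policies of the cleaning cascade."""

    min_negative_experiments: int = 4
    min_positive_responders: int = 1
    conflict_policy: str = "discard"  # discard | majority | positive_wins
    mhc_class: str | None = "I"  # None keeps all classes

    def __post_init__(self) -> None:
        if self.conflict_policy not in ("discard", "majority", "positive_wins"):
            raise ValueError(f"unknown conflict policy {self.conflict_policy!r}")


@dataclass
class CurationReport:
    """Per-step drop counts; conservation holds:
    n_input = n_kept_records + sum(drops) + n_rejects."""

    n_input: int = 0
    dropped_allele: int = 0
    dropped_mhc_class: int = 0
    dropped_missing_counts: int = 0
    dropped_negative_rule: int = 0
    dropped_positive_rule: int = 0
    dropped_conflict: int = 0
    merged_duplicates: int = 0
    n_rejects: int = 0
    n_kept_records: int = 0
    rejects: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total_dropped(self) -> int:
        return (
            self.dropped_allele
            + self.dropped_mhc_class
            + self.dropped_missing_counts
            + self.dropped_negative_rule
            + self.dropped_positive_rule
            + self.dropped_conflict
            + self.merged_duplicates
        )


def filter_records(
    records: Sequence[AssayRecord],
    policy: CurationPolicy | None = None,
) -> tuple[CuratedDataset, CurationReport]:
    """Apply the cleaning cascade; returns the dataset and a drop report.

    Malformed records (invalid peptide characters, unrecognized outcome)
    are collected into ``report.rejects`` rather than aborting the run.
    """
    policy = policy or CurationPolicy()
    report = CurationReport(n_input=len(records))
    logger.info(
        "negative-evidence rule: n_experiments >= %d (all negative)",
        policy.min_negative_experiments,
    )

    survivors: list[tuple[str, str, int, str]] = []  # peptide, allele, label, id
    for idx, rec in enumerate(records):
        rid = rec.record_id or f"record_{idx}"
        peptide = rec.peptide.strip().upper()
        if not peptide or not set(peptide) <= _VALID_RESIDUES:
            report.rejects.append((rid, f"invalid peptide {rec.peptide!r}"))
            continue
        if rec.qualitative_outcome not in ("positive", "negative"):
            report.rejects.append(
                (rid, f"unrecognized outcome {rec.qualitative_outcome!r}")
            )
            continue
        if policy.mhc_class is not None and rec.mhc_class.strip().upper() != policy.mhc_class:
            report.dropped_mhc_class += 1
            continue
        try:
            allele = normalize_allele(rec.allele)
        except AlleleError:
            report.dropped_allele += 1
            continue
        positive = rec.qualitative_outcome == "positive"
        if positive:
            if rec.n_subjects_responded is None:
                report.dropped_missing_counts += 1
                continue
            if rec.n_subjects_responded < policy.min_positive_responders:
                report.dropped_positive_rule += 1
                continue
        else:
            if rec.n_experiments is None:
                report.dropped_missing_counts += 1
                continue
            if rec.n_experiments < policy.min_negative_experiments:
                report.dropped_negative_rule += 1
                continue
        survivors.append((peptide, allele, int(positive), rid))

    # step 5: collapse duplicates of the same (peptide, allele)
    groups: dict[tuple[str, str], list[tuple[int, str]]] = {}
    order: list[tuple[str, str]] = []
    for peptide, allele, label, rid in survivors:
        key = (peptide, allele)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append((label, rid))

    instances: list[Instance] = []
    for key in order:
        members = groups[key]
        labels = {lab for lab, _ in members}
        ids = tuple(rid for _, rid in members)
        if len(labels) == 1:
            label = members[0][0]
        elif policy.conflict_policy == "discard":
            report.dropped_conflict += len(members)
            continue
        elif policy.conflict_policy == "positive_wins":
            label = 1
        else:  # majority; exact ties discarded
            n_pos = sum(lab for lab, _ in members)
            if 2 * n_pos == len(members):
                report.dropped_conflict += len(members)
                continue
            label = int(2 * n_pos > len(members))
        report.merged_duplicates += len(members) - 1
        instances.append(Instance(key[0], key[1], label, ids))

    report.n_rejects = len(report.rejects)
    report.n_kept_records = report.n_input - report.total_dropped - report.n_rejects
    logger.info(
        "curation: %d input -> %d instances (%d records dropped, %d rejects)",
        report.n_input, len(instances), report.total_dropped, report.n_rejects,
    )
    return CuratedDataset(instances=instances), report


def read_assay_tsv(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[AssayRecord]:
    """Read an assay-export TSV, renaming columns via ``column_map``.

    The map defaults to :data:`DEFAULT_COLUMN_MAP` (IEDB-ish headers);
    columns already in canonical form pass through unchanged.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={**DEFAULT_COLUMN_MAP, **(column_map or {})})
    records = []
    for idx, row in df.iterrows():
        def _int_or_none(v):
            return None if pd.isna(v) else int(v)

        records.append(
            AssayRecord(
                peptide=str(row["peptide"]),
                allele=str(row["allele"]),
                qualitative_outcome=str(row["qualitative_outcome"]),
                assay_class=str(row.get("assay_class", "other")),
                n_experiments=_int_or_none(row.get("n_experiments")),
                n_subjects_tested=_int_or_none(row.get("n_subjects_tested")),
                n_subjects_responded=_int_or_none(row.get("n_subjects_responded")),
                host=str(row.get("host", "Homo sapiens")),
                mhc_class=str(row.get("mhc_class", "I")),
                record_id=str(row.get("record_id", f"row_{idx}")),
            )
        )
    return records


# ---------------------------------------------------------------------------
# database similarity search
# ---------------------------------------------------------------------------


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass
class SimilarityHit:
    peptide: str
    score: float  # normalized to [.., 1.0]; 1.0 = identical
    raw_score: float
    rank: int
    metadata: dict = field(default_factory=dict)


def similarity_search(
    query: str,
    database: Sequence[str | tuple[str, dict]],
    top_n: int = 10,
) -> list[SimilarityHit]:
    """Rank database peptides by normalized global-alignment similarity.

    Similarity = S(q, d) / sqrt(S(q, q) * S(d, d)) under BLOSUM62 with
    gap open 11 / extend 1, so any sequence has self-similarity exactly 1.
    Ties keep database order.
    """
    if not database:
        raise ValueError("empty similarity database")
    query = query.strip().upper()
    if not query or not set(query) <= _VALID_RESIDUES:
        raise ValueError(f"invalid residues in query {query!r}")
    entries: list[tuple[str, dict]] = []
    for item in database:
        if isinstance(item, tuple):
            pep, meta = item
        else:
            pep, meta = item, {}
        pep = pep.strip().upper()
        if not pep or not set(pep) <= _VALID_RESIDUES:
            raise ValueError(f"invalid residues in database entry {pep!r}")
        entries.append((pep, meta))

    aligner = _aligner()
    self_q = aligner.score(query, query)
    hits = []
    for i, (pep, meta) in enumerate(entries):
        raw = aligner.score(query, pep)
        norm = raw / float(np.sqrt(self_q * aligner.score(pep, pep)))
        hits.append((norm, i, pep, raw, meta))
    hits.sort(key=lambda t: (-t[0], t[1]))
    return [
        SimilarityHit(peptide=pep, score=float(norm), raw_score=float(raw),
                      rank=r + 1, metadata=meta)
        for r, (norm, _, pep, raw, meta) in enumerate(hits[:top_n])
    ]

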