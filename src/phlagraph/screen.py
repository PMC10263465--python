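"""Multi-feature neoantigen screening from missense driver mutations.

Given a protein and a missense mutation, every 8-14-mer window covering
the mutated residue yields a mutant/wild-type peptide pair.  Each mutant
peptide is then pushed through a cascade of filters against each HLA
allele of interest:

* binding: predicted mutant %Rank < 2 (NetMHCpan-style percentile rank);
* differential agretopicity index DAI = IC50(WT) / IC50(MT) > 1, i.e. the
  mutation must improve binding over the wild-type counterpart;
* peptide-HLA complex stability %Rank < 2;
* antigen-processing (proteasomal cleavage + TAP transport) combined
  %Rank < 2;
* immunogenicity consensus: predicted positive by at least ``min_votes``
  (default 3) of the configured immunogenicity tools, where score-type
  tools vote at score >= 0.8 (inclusive) and rank-type tools at %Rank < 2.

Predictors are pluggable: anything satisfying :class:`PredictorSuite` can
supply the scores, so licensed external tools can be adapted in without
changing the cascade.  The filter is a pure conjunction, so its outcome is
independent of evaluation order; thresholds use strict inequalities for
ranks and DAI, inclusive for the 0.8 immunogenicity score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# mutations and peptide windows
# ---------------------------------------------------------------------------


@dataclass
class Mutation:
    """A missense mutation on a protein sequence (1-based position)."""

    gene: str
    protein_seq: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        self.protein_seq = self.protein_seq.strip().upper()
        self.ref_aa = self.ref_aa.upper()
        self.alt_aa = self.alt_aa.upper()
        if not 1 <= self.position <= len(self.protein_seq):
            raise ValueError(
                f"position {self.position} outside protein of length "
                f"{len(self.protein_seq)}"
            )
        observed = self.protein_seq[self.position - 1]
        if observed != self.ref_aa:
            raise ValueError(
                f"reference mismatch at position {self.position}: sequence has "
                f"{observed!r}, mutation says {self.ref_aa!r}"
            )
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt residues are identical (not missense)")

    @property
    def hgvs_p(self) -> str:
        return f"{self.gene}:p.{self.ref_aa}{self.position}{self.alt_aa}"


def mutate_protein(seq: str, position: int, ref_aa: str, alt_aa: str) -> str:
    """Apply a missense substitution; validates the reference residue."""
    seq = seq.strip().upper()
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside sequence of length {len(seq)}")
    observed = seq[position - 1]
    if observed != ref_aa.upper():
        raise ValueError(
            f"reference mismatch: position {position} is {observed!r}, "
            f"expected {ref_aa!r}"
        )
    return seq[: position - 1] + alt_aa.upper() + seq[position:]


@dataclass
class PeptidePair:
    """A mutant/wild-type peptide window over the mutated residue."""

    mt_peptide: str
    wt_peptide: str
    offset_of_mutation: int  # 1-based within the peptide

    def __post_init__(self) -> None:
        if len(self.mt_peptide) != len(self.wt_peptide):
            raise ValueError("MT and WT peptides must have equal length")
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(self.mt_peptide, self.wt_peptide))
            if a != b
        ]
        if diffs != [self.offset_of_mutation]:
            raise ValueError(
                f"peptides must differ exactly at offset {self.offset_of_mutation}, "
                f"differ at {diffs}"
            )

    @property
    def length(self) -> int:
        return len(self.mt_peptide)


def extract_peptide_pairs(
    wt_seq: str,
    mt_seq: str,
    position: int,
    lengths: Sequence[int] = tuple(range(8, 15)),
) -> list[PeptidePair]:
    """Every window of each length that covers the mutated position.

    Windows are ordered by (length, start); identical (MT, WT) string
    pairs arising from repetitive sequence are deduplicated, keeping the
    first occurrence.
    """
    wt_seq, mt_seq = wt_seq.strip().upper(), mt_seq.strip().upper()
    if len(wt_seq) != len(mt_seq):
        raise ValueError("WT and MT sequences must have equal length")
    diffs = [i + 1 for i, (a, b) in enumerate(zip(wt_seq, mt_seq)) if a != b]
    if diffs != [position]:
        raise ValueError(
            f"sequences must differ only at position {position}, differ at {diffs}"
        )
    pairs: list[PeptidePair] = []
    seen: set[tuple[str, str]] = set()
    n = len(wt_seq)
    for L in lengths:
        start_lo = max(1, position - L + 1)
        start_hi = min(position, n - L + 1)
        for start in range(start_lo, start_hi + 1):
            mt = mt_seq[start - 1 : start - 1 + L]
            wt = wt_seq[start - 1 : start - 1 + L]
            if (mt, wt) in seen:
                continue
            seen.add((mt, wt))
            pairs.append(
                PeptidePair(mt_peptide=mt, wt_peptide=wt,
                            offset_of_mutation=position - start + 1)
            )
    return pairs


# ---------------------------------------------------------------------------
# predictor contract and thresholds
# ---------------------------------------------------------------------------


class PredictorSuite(Protocol):
    """Contract that any backing predictor stack must satisfy.

    All methods must be pure functions of their inputs; %Ranks lie in
    [0, 100] and IC50 values are positive nanomolar concentrations.
    ``immunogenicity_tool_types`` maps each tool name to ``"score"``
    (higher is better, in [0, 1]) or ``"rank"`` (lower is better).
    """

    immunogenicity_tool_types: dict[str, str]

    def binding(self, peptide: str, allele: str) -> tuple[float, float]:
        """Return (ic50_nM, percent_rank)."""
        ...

    def stability(self, peptide: str, allele: str) -> float:
        """Return the complex-stability percent rank."""
        ...

    def processing(self, peptide: str, allele: str) -> float:
        """Return the combined cleavage+TAP percent rank."""
        ...

    def immunogenicity(self, peptide: str, allele: str) -> dict[str, float]:
        """Return tool_name -> score-or-rank."""
        ...


@dataclass
class FilterThresholds:
    """Cascade thresholds; rank/DAI comparisons are strict, score inclusive."""

    binding_rank_max: float = 2.0
    dai_min: float = 1.0
    stability_rank_max: float = 2.0
    processing_rank_max: float = 2.0
    immuno_score_min: float = 0.8
    prime_rank_max: float = 2.0
    min_votes: int = 3

    def __post_init__(self) -> None:
        values = (
            self.binding_rank_max, self.dai_min, self.stability_rank_max,
            self.processing_rank_max, self.immuno_score_min,
            self.prime_rank_max, self.min_votes,
        )
        if any(v <= 0 for v in values):
            raise ValueError("all thresholds must be positive")


def compute_dai(ic50_wt: float, ic50_mt: float) -> float:
    """Differential agretopicity index: IC50(WT) / IC50(MT).

    Values above 1 mean the mutant binds more strongly than its wild-type
    counterpart.
    """
    if ic50_wt <= 0 or ic50_mt <= 0:
        raise ValueError(f"IC50 values must be positive, got {ic50_wt}, {ic50_mt}")
    return ic50_wt / ic50_mt


def vote_immunogenicity(
    scores: dict[str, float],
    thresholds: FilterThresholds,
    tool_types: dict[str, str] | None = None,
) -> int:
    """Count tools calling the peptide immunogenic.

    Score-type tools vote at ``score >= immuno_score_min`` (inclusive,
    matching the published 0.8 cutoff); rank-type tools vote at
    ``rank < prime_rank_max``.  Tool types default to name-based
    inference: names containing "rank" are rank-type.
    """
    if not scores:
        raise ValueError("no immunogenicity tools supplied")
    votes = 0
    for tool, value in scores.items():
        if tool_types is not None:
            ttype = tool_types.get(tool)
            if ttype not in ("score", "rank"):
                raise ValueError(f"unknown tool type {ttype!r} for {tool!r}")
        else:
            ttype = "rank" if "rank" in tool.lower() else "score"
        if ttype == "rank":
            votes += int(value < thresholds.prime_rank_max)
        else:
            votes += int(value >= thresholds.immuno_score_min)
    return votes


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


@dataclass
class CandidateNeoantigen:
    """One mutant peptide x allele candidate with all scores and flags."""

    gene: str
    mutation: str  # HGVS-style p. notation
    allele: str
    pair: PeptidePair
    ic50_mt: float = np.nan
    ic50_wt: float = np.nan
    binding_rank_mt: float = np.nan
    binding_rank_wt: float = np.nan
    dai: float = np.nan
    stability_rank: float = np.nan
    processing_rank: float = np.nan
    immuno_scores: dict[str, float] = field(default_factory=dict)
    votes: int = 0
    flags: dict[str, bool] = field(default_factory=dict)
    passed: bool = False
    error: str | None = None


FILTER_NAMES = ("binding", "dai", "stability", "processing", "immunogenicity")


def _evaluate_candidate(
    cand: CandidateNeoantigen,
    suite: PredictorSuite,
    thresholds: FilterThresholds,
) -> None:
    mt, wt, allele = cand.pair.mt_peptide, cand.pair.wt_peptide, cand.allele
    cand.ic50_mt, cand.binding_rank_mt = suite.binding(mt, allele)
    # WT binding is recorded for DAI but is not itself a filter.
    cand.ic50_wt, cand.binding_rank_wt = suite.binding(wt, allele)
    cand.dai = compute_dai(cand.ic50_wt, cand.ic50_mt)
    cand.stability_rank = suite.stability(mt, allele)
    cand.processing_rank = suite.processing(mt, allele)
    cand.immuno_scores = dict(suite.immunogenicity(mt, allele))
    tool_types = getattr(suite, "immunogenicity_tool_types", None)
    cand.votes = vote_immunogenicity(cand.immuno_scores, thresholds, tool_types)
    cand.flags = {
        "binding": cand.binding_rank_mt < thresholds.binding_rank_max,
        "dai": cand.dai > thresholds.dai_min,
        "stability": cand.stability_rank < thresholds.stability_rank_max,
        "processing": cand.processing_rank < thresholds.processing_rank_max,
        "immunogenicity": cand.votes >= thresholds.min_votes,
    }
    cand.passed = all(cand.flags.values())


def screen_candidates(
    mutations: Sequence[Mutation],
    alleles: Sequence[str],
    suite: PredictorSuite,
    thresholds: FilterThresholds | None = None,
    keep_all: bool = False,
    lengths: Sequence[int] = tuple(range(8, 15)),
) -> tuple[list[CandidateNeoantigen], dict]:
    """Run the full cascade over mutations x alleles x peptide windows.

    Returns the candidate list (only passing candidates unless
    ``keep_all``) and a summary dict with per-filter survivor counts.
    A predictor failure marks that candidate as errored and the run
    continues.
    """
    thresholds = thresholds or FilterThresholds()
    candidates: list[CandidateNeoantigen] = []
    n_errors = 0
    for mut in mutations:
        mt_seq = mutate_protein(mut.protein_seq, mut.position, mut.ref_aa, mut.alt_aa)
        pairs = extract_peptide_pairs(mut.protein_seq, mt_seq, mut.position, lengths)
        for allele in alleles:
            for pair in pairs:
                cand = CandidateNeoantigen(
                    gene=mut.gene, mutation=mut.hgvs_p, allele=allele, pair=pair
                )
                try:
                    _evaluate_candidate(cand, suite, thresholds)
                except Exception as exc:  # predictor failure: record, continue
                    cand.error = str(exc)
                    n_errors += 1
                candidates.append(cand)

    evaluated = [c for c in candidates if c.error is None]
    summary = {
        "n_candidates": len(candidates),
        "n_errors": n_errors,
        "n_passed": sum(c.passed for c in evaluated),
        "per_filter_pass": {
            name: sum(c.flags[name] for c in evaluated) for name in FILTER_NAMES
        },
        "thresholds": thresholds.__dict__.copy(),
    }
    if n_errors:
        logger.warning("%d candidate(s) failed predictor evaluation", n_errors)
    if keep_all:
        return candidates, summary
    return [c for c in evaluated if c.passed], summary


def candidates_to_frame(candidates: Sequence[CandidateNeoantigen]) -> pd.DataFrame:
    """Flatten candidates into a table (one row per peptide x allele)."""
    rows = []
    for c in candidates:
        row = {
            "gene": c.gene, "mutation": c.mutation, "allele": c.allele,
            "mt_peptide": c.pair.mt_peptide, "wt_peptide": c.pair.wt_peptide,
            "length": c.pair.length, "mutation_offset": c.pair.offset_of_mutation,
            "ic50_mt": c.ic50_mt, "ic50_wt": c.ic50_wt,
            "binding_rank_mt": c.binding_rank_mt,
            "binding_rank_wt": c.binding_rank_wt,
            "dai": c.dai, "stability_rank": c.stability_rank,
            "processing_rank": c.processing_rank, "votes": c.votes,
            "passed": c.passed, "error": c.error or "",
        }
        for name in FILTER_NAMES:
            row[f"pass_{name}"] = c.flags.get(name, False)
        for tool, value in c.immuno_scores.items():
            row[f"immuno_{tool}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def heatmap_matrix(
    candidates: Sequence[CandidateNeoantigen], value: str = "binding_rank_mt"
) -> pd.DataFrame:
    """Allele x mutant-peptide matrix of one score, for heatmap export.

    All candidates must come from the same mutation; missing allele x
    peptide combinations are left empty (NaN).
    """
    if not candidates:
        raise ValueError("no candidates to tabulate")
    mutations = {c.mutation for c in candidates}
    if len(mutations) > 1:
        raise ValueError(f"candidates span multiple mutations: {sorted(mutations)}")
    df = candidates_to_frame(candidates)
    if value not in df.columns:
        raise ValueError(f"unknown value column {value!r}")
    peptide_order = list(dict.fromkeys(df["mt_peptide"]))
    mat = df.pivot_table(
        index="allele", columns="mt_peptide", values=value, aggfunc="first"
    )
    return mat.reindex(columns=peptide_order)
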