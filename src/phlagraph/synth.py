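"""Seeded generators for every input format the toolkit consumes.

These generators exist so the whole pipeline — embedding, graph building,
training, curation, screening — can be exercised end-to-end with no
external downloads.  Each generator is a pure function of its seed.

The labeled-dataset generator plants a biologically shaped signal: the
log-odds of immunogenicity depend on the physicochemical character of the
peptide residues at position 2 and the C-terminus (the canonical class-I
anchor positions, which dominate sequence conservation in validated
epitope collections) plus a per-allele offset.  Ground-truth parameters
are returned alongside the data so recovery and calibration tests can
compare against the generating model.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
import numpy as np

from .aaindex import RESIDUES, AminoAcidFeatureTable
from .curation import AssayRecord, CuratedDataset, Instance
from .graph import PseudoSequenceTable, normalize_allele
from .screen import Mutation


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-signal benchmark dataset."""

    seed: int = 0
    n_peptides: int = 2000
    length_range: tuple[int, int] = (8, 14)
    n_alleles: int = 8
    planted_effect_size: float = 2.0
    allele_offset_sd: float = 7.0
    label_noise: float = 0.5
    n_assay_records: int = 50

    def __post_init__(self) -> None:
        if self.n_peptides < 1 or self.n_alleles < 1 or self.n_assay_records < 1:
            raise ValueError("sizes must be positive")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length range {self.length_range}")


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


def gen_pseudo_table(n_alleles: int, seed: int = 0) -> PseudoSequenceTable:
    """Synthetic allele -> 34-mer pseudo-sequence table."""
    if n_alleles < 1:
        raise ValueError("need at least one allele")
    rng = np.random.default_rng(seed)
    genes = "ABC"
    mapping = {}
    for i in range(n_alleles):
        name = f"HLA-{genes[i % 3]}*{i // 3 + 1:02d}:01"
        mapping[name] = _random_peptide(rng, 34)
    return PseudoSequenceTable(mapping=mapping)


@dataclass
class PlantedGroundTruth:
    """Generating parameters of the planted-signal dataset."""

    projection: np.ndarray  # unit vector over embedding dims
    residue_scores: dict[str, float]  # standardized w . f(residue)
    allele_offsets: dict[str, float]
    logits: np.ndarray  # true log-odds per instance
    labels: np.ndarray

    def anchor_term(self, peptide: str) -> float:
        s = self.residue_scores
        return (s[peptide[1]] + s[peptide[-1]]) / np.sqrt(2.0)


def gen_labeled_dataset(
    cfg: SyntheticConfig,
    emb: AminoAcidFeatureTable,
    pseudo_table: PseudoSequenceTable,
) -> tuple[CuratedDataset, PlantedGroundTruth]:
    """Planted-signal labeled peptide-HLA dataset.

    label ~ Bernoulli(sigmoid(z)) with
    ``z = effect * (s(p2) + s(pL)) / sqrt(2) + allele_offset + noise * eps``,
    where ``s`` is a seeded random projection of the residue embedding,
    standardized over the 20 residues so ``effect`` is in log-odds units.
    """
    rng = np.random.default_rng(cfg.seed)
    w = rng.standard_normal(emb.n_components)
    w /= np.linalg.norm(w)
    raw = np.array([emb.embedding[r] @ w for r in RESIDUES])
    std = raw.std()
    if std == 0:
        raise ValueError("degenerate embedding: zero variance along projection")
    scores = {r: float((v - raw.mean()) / std) for r, v in zip(RESIDUES, raw)}
    alleles = pseudo_table.alleles[: cfg.n_alleles]
    if len(alleles) < cfg.n_alleles:
        raise ValueError("pseudo-sequence table has fewer alleles than requested")
    # Offsets are centered over the allele panel so the overall class
    # balance stays near 1:1 regardless of the seed's particular draws.
    draws = rng.normal(0.0, cfg.allele_offset_sd, size=len(alleles))
    draws -= draws.mean()
    offsets = {a: float(d) for a, d in zip(alleles, draws)}
    if cfg.planted_effect_size == 0 and cfg.label_noise == 0:
        raise ValueError("zero effect and zero noise give degenerate labels")
    if cfg.planted_effect_size != 0 and cfg.label_noise == 0:
        warnings.warn("zero label noise: labels are near-deterministic in z")

    lo, hi = cfg.length_range
    instances: list[Instance] = []
    logits = np.empty(cfg.n_peptides)
    labels = np.empty(cfg.n_peptides, dtype=int)
    seen: set[tuple[str, str]] = set()
    i = 0
    while i < cfg.n_peptides:
        length = int(rng.integers(lo, hi + 1))
        pep = _random_peptide(rng, length)
        allele = alleles[int(rng.integers(len(alleles)))]
        if (pep, allele) in seen:
            continue
        seen.add((pep, allele))
        anchor = (scores[pep[1]] + scores[pep[-1]]) / np.sqrt(2.0)
        z = (
            cfg.planted_effect_size * anchor
            + offsets[allele]
            + cfg.label_noise * rng.standard_normal()
        )
        y = int(rng.random() < 1.0 / (1.0 + np.exp(-z)))
        logits[i] = z
        labels[i] = y
        instances.append(Instance(pep, allele, y, (f"synthetic_{i}",)))
        i += 1
    truth = PlantedGroundTruth(
        projection=w, residue_scores=scores, allele_offsets=offsets,
        logits=logits, labels=labels,
    )
    return CuratedDataset(instances=instances), truth


# ---------------------------------------------------------------------------
# assay records with an embedded survivor oracle
# ---------------------------------------------------------------------------


def gen_assay_records(
    cfg: SyntheticConfig,
) -> tuple[list[AssayRecord], list[Instance]]:
    """Assay records that exercise every branch of the curation cascade.

    Returns the records plus the expected surviving instances, computed
    from the construction plan itself (not by running the filter), so the
    list serves as an independent oracle for ``filter_records``.
    """
    rng = np.random.default_rng(cfg.seed)
    alleles = [f"HLA-A*{i + 1:02d}:01" for i in range(4)]
    used: set[str] = set()

    def fresh_peptide() -> str:
        while True:
            pep = _random_peptide(rng, 9)
            if pep not in used:
                used.add(pep)
                return pep

    records: list[AssayRecord] = []
    expected: list[Instance] = []
    rid = iter(f"syn_{i}" for i in range(10_000))

    def add(keep: bool, label: int | None = None, **kw) -> AssayRecord:
        rec = AssayRecord(record_id=next(rid), **kw)
        records.append(rec)
        if keep:
            expected.append(
                Instance(rec.peptide.upper(), normalize_allele(rec.allele),
                         int(label), (rec.record_id,))
            )
        return rec

    # branch coverage (each block uses a fresh peptide so blocks don't interact)
    add(False, peptide=fresh_peptide(), allele="HLA-A2",  # 2-digit allele
        qualitative_outcome="positive", n_subjects_responded=3)
    add(False, peptide=fresh_peptide(), allele=alleles[0],  # missing count
        qualitative_outcome="positive", n_subjects_responded=None)
    add(False, peptide=fresh_peptide(), allele=alleles[0],
        qualitative_outcome="negative", n_experiments=None)
    for n_exp, keep in ((3, False), (4, True), (5, True)):
        add(keep, label=0, peptide=fresh_peptide(), allele=alleles[1],
            qualitative_outcome="negative", n_experiments=n_exp)
    for n_resp, keep in ((0, False), (1, True), (2, True)):
        add(keep, label=1, peptide=fresh_peptide(), allele=alleles[1],
            qualitative_outcome="positive", n_subjects_tested=5,
            n_subjects_responded=n_resp)
    # concordant duplicate -> single instance
    dup = fresh_peptide()
    add(True, label=1, peptide=dup, allele=alleles[2],
        qualitative_outcome="positive", n_subjects_responded=1)
    add(False, peptide=dup, allele=alleles[2],
        qualitative_outcome="positive", n_subjects_responded=4)
    # discordant duplicate -> both discarded under the default policy
    conflict = fresh_peptide()
    add(False, peptide=conflict, allele=alleles[2],
        qualitative_outcome="positive", n_subjects_responded=2)
    add(False, peptide=conflict, allele=alleles[2],
        qualitative_outcome="negative", n_experiments=6)
    # MHC class II record
    add(False, peptide=fresh_peptide(), allele="HLA-DRB1*04:01",
        qualitative_outcome="positive", n_subjects_responded=2, mhc_class="II")
    # malformed peptide -> reject
    rec = AssayRecord(record_id=next(rid), peptide="ACDX1Z", allele=alleles[0],
                      qualitative_outcome="positive", n_subjects_responded=1)
    records.append(rec)

    # random filler with known outcomes
    while len(records) < cfg.n_assay_records:
        pep = fresh_peptide()
        allele = alleles[int(rng.integers(len(alleles)))]
        if rng.random() < 0.5:
            n_resp = int(rng.integers(0, 4))
            add(n_resp >= 1, label=1, peptide=pep, allele=allele,
                qualitative_outcome="positive", n_subjects_tested=6,
                n_subjects_responded=n_resp)
        else:
            n_exp = int(rng.integers(1, 8))
            add(n_exp >= 4, label=0, peptide=pep, allele=allele,
                qualitative_outcome="negative", n_experiments=n_exp)
    return records, expected


# ---------------------------------------------------------------------------
# deterministic toy predictor suite
# ---------------------------------------------------------------------------


class ToyPredictorSuite:
    """Hash-based stand-in for an external binding/stability/processing/
    immunogenicity predictor stack.

    Every score is a pure deterministic function of (seed, channel,
    peptide, allele): a BLAKE2b digest mapped to a plausible range
    (IC50 log-uniform on [1, 50000] nM, %Ranks uniform on [0, 100],
    immunogenicity scores uniform on [0, 1]).  Useful for exercising and
    snapshot-testing the screening cascade without licensed tools.
    """

    immunogenicity_tool_types = {
        "toy_cnn_a": "score",
        "toy_cnn_b": "score",
        "toy_gnn": "score",
        "toy_rank": "rank",
    }

    def __init__(self, seed: int = 0) -> None:
        self.seed = int(seed)

    def _u(self, channel: str, peptide: str, allele: str) -> float:
        key = f"{self.seed}|{channel}|{peptide.upper()}|{allele}".encode()
        digest = hashlib.blake2b(key, digest_size=8).digest()
        return int.from_bytes(digest, "big") / float(2**64)

    def binding(self, peptide: str, allele: str) -> tuple[float, float]:
        u = self._u("ic50", peptide, allele)
        ic50 = float(np.exp(np.log(1.0) + u * (np.log(50_000.0) - np.log(1.0))))
        rank = 100.0 * self._u("bind_rank", peptide, allele)
        return ic50, rank

    def stability(self, peptide: str, allele: str) -> float:
        return 100.0 * self._u("stab_rank", peptide, allele)

    def processing(self, peptide: str, allele: str) -> float:
        return 100.0 * self._u("proc_rank", peptide, allele)

    def immunogenicity(self, peptide: str, allele: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for tool, ttype in self.immunogenicity_tool_types.items():
            u = self._u(f"immuno_{tool}", peptide, allele)
            out[tool] = 100.0 * u if ttype == "rank" else u
        return out


def gen_toy_predictor_suite(seed: int = 0) -> ToyPredictorSuite:
    return ToyPredictorSuite(seed=seed)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------


def gen_mutations(
    n: int, protein_length: int = 41, seed: int = 0
) -> tuple[list[Mutation], str]:
    """Random missense mutations on random proteins, plus a FASTA string.

    When ``n >= 5`` the set is guaranteed to include a mutation at
    position 1 and one at the final position, for window-boundary tests.
    ``protein_length >= 27`` guarantees a full interior window set for at
    least one mutation.
    """
    if protein_length < 8:
        raise ValueError("protein_length must allow at least one 8-mer window")
    rng = np.random.default_rng(seed)
    mutations: list[Mutation] = []
    fasta_lines: list[str] = []
    for i in range(n):
        seq = _random_peptide(rng, protein_length)
        if n >= 5 and i == 0:
            pos = 1
        elif n >= 5 and i == 1:
            pos = protein_length
        else:
            pos = int(rng.integers(1, protein_length + 1))
        ref = seq[pos - 1]
        alt = ref
        while alt == ref:
            alt = RESIDUES[int(rng.integers(20))]
        gene = f"GENE{i + 1}"
        mutations.append(
            Mutation(gene=gene, protein_seq=seq, position=pos, ref_aa=ref, alt_aa=alt)
        )
        fasta_lines.append(f">{gene}")
        fasta_lines.append(seq)
    return mutations, "\n".join(fasta_lines) + "\n"


# ---------------------------------------------------------------------------
# AAindex-style fixture text
# ---------------------------------------------------------------------------

_I_HEADER = "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"
_I_ORDER = "ARNDCQEGHILKMFPSTWYV"  # firsts then seconds of the header pairs


def gen_aaindex_text(
    n_complete: int = 27, n_incomplete: int = 2, seed: int = 0
) -> str:
    """Synthetic AAindex1-format flat file text.

    Record values are random but deterministic in the seed; ``n_incomplete``
    records carry a literal ``NA`` so the missing-value path is exercised.
    """
    rng = np.random.default_rng(seed)
    chunks = []
    total = n_complete + n_incomplete
    for i in range(total):
        acc = f"SYNX{i + 1:03d}"
        values = np.round(rng.normal(0.0, 2.0, size=20), 3)
        tokens = [f"{v:.3f}" for v in values]
        if i >= n_complete:  # make the trailing records incomplete
            tokens[int(rng.integers(20))] = "NA"
        first = "    " + "    ".join(f"{t:>7s}" for t in tokens[:10])
        second = "    " + "    ".join(f"{t:>7s}" for t in tokens[10:])
        chunks.append(
            "\n".join(
                [
                    f"H {acc}",
                    f"D Synthetic physicochemical index {i + 1}",
                    "R",
                    "A Synthetic fixture",
                    "T Generated index table",
                    "J none",
                    _I_HEADER,
                    first,
                    second,
                    "//",
                ]
            )
        )
    return "\n".join(chunks) + "\n"
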