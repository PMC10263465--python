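"""Peptide-HLA graph construction.

A class-I HLA allele is represented by the 34 residues that line the
peptide-binding groove (its pseudo-sequence); a peptide of length L and its
allele become a fully connected directed graph over L + 34 residue nodes
plus one virtual readout node connected to everything.  Each node carries
the 20-dim physicochemical embedding of its residue plus a 3-way one-hot
(peptide / HLA / virtual); the virtual node's embedding part is all zeros.

Node order is fixed: peptide residues N-to-C, then pseudo-sequence
positions 1-34, then the virtual node last.  The edge set is every ordered
pair of distinct nodes, so a graph with N+1 nodes has (N+1)*N directed
edges and no self-loops.
"""

from __future__ import annotations

import difflib
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .aaindex import AminoAcidFeatureTable, embed_residue

PSEUDO_SEQUENCE_LENGTH = 34

NODE_TYPE_PEPTIDE = "peptide"
NODE_TYPE_HLA = "hla"
NODE_TYPE_VIRTUAL = "virtual"
_TYPE_ONEHOT = {
    NODE_TYPE_PEPTIDE: (1.0, 0.0, 0.0),
    NODE_TYPE_HLA: (0.0, 1.0, 0.0),
    NODE_TYPE_VIRTUAL: (0.0, 0.0, 1.0),
}

class AlleleError(ValueError):
    """Raised for unparsable or insufficiently resolved HLA allele names."""


def normalize_allele(name: str) -> str:
    """Normalize an HLA class-I allele name to ``HLA-A*02:01`` form.

    Accepts common spellings ("A0201", "HLA-A*0201", "HLA-A*02:01").
    At least 4 digits of resolution (2-digit group + 2-digit protein) are
    required; names like "HLA-A2" are rejected.
    """
    if not name or not name.strip():
        raise AlleleError("empty allele name")
    s = name.strip().upper()
    if s.startswith("HLA-"):
        s = s[4:]
    if "*" in s:
        gene, digits_part = (part.strip() for part in s.split("*", 1))
    else:
        m = re.match(r"^([A-Z]+)(.*)$", s)
        if m is None:
            raise AlleleError(f"unparsable HLA allele name: {name!r}")
        gene, digits_part = m.group(1), m.group(2).strip()
    if not gene or not re.fullmatch(r"[A-Z]+[0-9]*", gene):
        raise AlleleError(f"unparsable HLA allele name: {name!r}")
    if not re.fullmatch(r"[0-9:]+", digits_part):
        raise AlleleError(f"unparsable HLA allele name: {name!r}")
    if ":" in digits_part:
        groups = digits_part.split(":")
        if len(groups) < 2 or not all(g.isdigit() and g for g in groups[:2]):
            raise AlleleError(f"unparsable HLA allele name: {name!r}")
        g1, g2 = groups[0], groups[1]
    else:
        digits = digits_part
        if not digits.isdigit() or len(digits) < 4:
            raise AlleleError(
                f"allele {name!r} lacks 4-digit resolution (got {digits_part!r})"
            )
        # Digit fields are two characters each at 4-digit resolution; longer
        # first fields (e.g. A*110:01 style) must be written with colons.
        g1, g2 = digits[:2], digits[2:]
    if len(g1) < 2 or len(g2) < 2:
        raise AlleleError(
            f"allele {name!r} lacks 4-digit resolution"
        )
    return f"HLA-{gene}*{int(g1):02d}:{int(g2):02d}"


@dataclass
class PseudoSequenceTable:
    """Mapping from canonical allele name to its 34-mer pseudo-sequence."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        canon: dict[str, str] = {}
        for allele, seq in self.mapping.items():
            seq = seq.strip().upper()
            if len(seq) != PSEUDO_SEQUENCE_LENGTH:
                raise ValueError(
                    f"pseudo-sequence for {allele} has length {len(seq)}, "
                    f"expected {PSEUDO_SEQUENCE_LENGTH}"
                )
            canon[normalize_allele(allele)] = seq
        self.mapping = canon

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, allele: str) -> bool:
        try:
            return normalize_allele(allele) in self.mapping
        except AlleleError:
            return False

    @property
    def alleles(self) -> list[str]:
        return list(self.mapping)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PseudoSequenceTable":
        """Read a two-column TSV (allele, 34-mer); '#' lines are comments."""
        mapping: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"malformed pseudo-sequence line: {line!r}")
            mapping[fields[0]] = fields[1]
        return cls(mapping=mapping)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# allele\tpseudo_sequence"]
        lines += [f"{a}\t{s}" for a, s in self.mapping.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def lookup_pseudo_sequence(allele: str, table: PseudoSequenceTable) -> str:
    """Return the 34-mer for ``allele`` (any accepted spelling)."""
    canonical = normalize_allele(allele)
    try:
        return table.mapping[canonical]
    except KeyError:
        near = difflib.get_close_matches(canonical, table.alleles, n=3, cutoff=0.0)
        raise KeyError(
            f"allele {canonical} not in pseudo-sequence table; nearest: {near}"
        ) from None


@dataclass
class PHLAGraph:
    """Fully connected peptide-HLA graph with a virtual readout node."""

    node_features: np.ndarray  # (N+1, emb_dim + 3)
    node_types: list[str]
    edges: np.ndarray  # (E, 2) directed, no self-loops
    peptide_length: int
    allele: str

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def virtual_index(self) -> int:
        return self.n_nodes - 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_features": self.node_features.tolist(),
                "node_types": self.node_types,
                "edges": self.edges.tolist(),
                "peptide_length": self.peptide_length,
                "allele": self.allele,
            }
        )


def complete_digraph_edges(n_nodes: int) -> np.ndarray:
    """All ordered pairs of distinct nodes among ``n_nodes`` nodes."""
    idx = np.arange(n_nodes)
    src = np.repeat(idx, n_nodes)
    dst = np.tile(idx, n_nodes)
    keep = src != dst
    return np.stack([src[keep], dst[keep]], axis=1)


def build_phla_graph(
    peptide: str,
    allele: str,
    table: PseudoSequenceTable,
    emb: AminoAcidFeatureTable,
    length_range: tuple[int, int] = (8, 14),
) -> PHLAGraph:
    """Build the complete pHLA graph for one peptide-allele pair.

    Raises if the peptide length falls outside ``length_range`` or if the
    peptide contains a non-letter character.
    """
    peptide = peptide.strip().upper()
    lo, hi = length_range
    if not (lo <= len(peptide) <= hi):
        raise ValueError(
            f"peptide length {len(peptide)} outside allowed range [{lo}, {hi}]"
        )
    if not peptide.isalpha():
        raise ValueError(f"peptide contains invalid characters: {peptide!r}")
    pseudo = lookup_pseudo_sequence(allele, table)
    dim = emb.n_components
    residues = list(peptide) + list(pseudo)
    types = (
        [NODE_TYPE_PEPTIDE] * len(peptide)
        + [NODE_TYPE_HLA] * PSEUDO_SEQUENCE_LENGTH
        + [NODE_TYPE_VIRTUAL]
    )
    n_nodes = len(residues) + 1
    features = np.zeros((n_nodes, dim + 3))
    for i, res in enumerate(residues):
        vec, _ = embed_residue(res, emb)
        features[i, :dim] = vec
    for i, t in enumerate(types):
        features[i, dim:] = _TYPE_ONEHOT[t]
    return PHLAGraph(
        node_features=features,
        node_types=types,
        edges=complete_digraph_edges(n_nodes),
        peptide_length=len(peptide),
        allele=normalize_allele(allele),
    )
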