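"""phlagraph: peptide-HLA graph toolkit for neoantigen immunogenicity.

Components:

* :mod:`phlagraph.aaindex` — AAindex1 parsing and the robust-scaled PCA
  residue embedding.
* :mod:`phlagraph.graph` — fully connected peptide-HLA graphs with a
  virtual readout node.
* :mod:`phlagraph.nn` / :mod:`phlagraph.model` — the graph attention
  classifier (training, grid search, cross-validation, batch prediction).
* :mod:`phlagraph.curation` — assay-record cleaning into a labeled
  training set, and database similarity search.
* :mod:`phlagraph.screen` — the multi-feature neoantigen screening
  cascade with pluggable predictors.
* :mod:`phlagraph.metrics` — sensitivity, F1, TopK, ROC/AUC.
* :mod:`phlagraph.synth` — seeded generators for every input format.
"""

from importlib import resources

from .aaindex import (
    AminoAcidFeatureTable,
    build_embedding,
    drop_missing,
    embed_residue,
    fit_pca_embedding,
    parse_aaindex,
    robust_normalize,
)
from .curation import (
    AssayRecord,
    CuratedDataset,
    CurationPolicy,
    filter_records,
    similarity_search,
)
from .graph import (
    PHLAGraph,
    PseudoSequenceTable,
    build_phla_graph,
    lookup_pseudo_sequence,
    normalize_allele,
)
from .metrics import LabeledScores, f1, roc_auc, sensitivity, topk
from .model import (
    ImmunoGNNModel,
    ModelConfig,
    cross_validate,
    grid_search,
    predict_batch,
    stratified_split,
    train,
)
from .screen import (
    CandidateNeoantigen,
    FilterThresholds,
    Mutation,
    compute_dai,
    extract_peptide_pairs,
    heatmap_matrix,
    mutate_protein,
    screen_candidates,
    vote_immunogenicity,
)
from .synth import (
    SyntheticConfig,
    gen_assay_records,
    gen_labeled_dataset,
    gen_mutations,
    gen_pseudo_table,
    gen_toy_predictor_suite,
)

__version__ = "0.1.0"


def packaged_aaindex_path():
    """Path to the packaged synthetic AAindex1-format fixture file."""
    return resources.files("phlagraph.data") / "aaindex_synthetic.txt"


def packaged_pseudo_path():
    """Path to the packaged synthetic pseudo-sequence table."""
    return resources.files("phlagraph.data") / "pseudo_synthetic.tsv"
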