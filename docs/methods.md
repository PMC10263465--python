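# Methods

This note documents the models and procedures implemented in `phlagraph`,
the choices made where the underlying methodology leaves details open, and
what the synthetic benchmarks do and do not demonstrate.

## Residue featurization

Amino acids are featurized from a table of physicochemical indices in
AAindex1 flat format (one real value per index per standard residue, `NA`
for missing). The pipeline is:

1. **Missing-value removal** — any index with at least one missing residue
   value is discarded entirely (no imputation).
2. **Robust scaling** — each surviving index is scaled over the 20
   residues as `(x − median) / IQR`, with quartiles computed by linear
   interpolation. "Robust scaling" has several conventions; we use the
   median/IQR scaler because it is the standard robust alternative to
   z-scoring and is insensitive to the heavy-tailed indices in these
   collections. Indices with zero IQR carry no rank information at
   20-residue resolution and are dropped with a logged warning.
3. **PCA** — the resulting 20 × F matrix (residues as observations) is
   column-centered and decomposed; the scores of the top 20 principal
   components become the per-residue embedding.

Numerical conventions worth knowing:

* A centered matrix with 20 rows has rank ≤ 19, so when 20 components are
  requested the final component has numerically zero variance. This is
  permitted (with its variance ratio logged) rather than treated as an
  error, so the embedding width stays at the conventional 20.
* PCA is sign-ambiguous per component. We pin each loading column so its
  largest-magnitude entry is positive, making the embedding bitwise
  reproducible across runs and BLAS builds.
* Variance is *not* re-standardized between robust scaling and PCA.
* Nonstandard one-letter codes (B, J, O, U, X, Z) embed as the zero vector
  with a flag rather than raising, so datasets containing rare codes
  degrade gracefully.

## The peptide–HLA graph

A class-I allele is represented by the 34 binding-groove residues of its
pseudo-sequence (a fixed-length allele encoding; the packaged table is a
synthetic stand-in in the same two-column TSV format, since we do not
redistribute predictor data). A peptide of length L (8–14 by default) and
its allele form a graph with L + 34 residue nodes plus one virtual node:

* node order: peptide N→C, pseudo-sequence positions 1–34, virtual last;
* edges: every ordered pair of distinct nodes — (N+1)·N directed edges,
  no self-loops. Because the true contact topology of the complex is
  unknown without a structure, the graph is deliberately complete and the
  attention mechanism learns which pairs matter;
* features: the 20-dim embedding concatenated with a 3-way one-hot node
  type (peptide / HLA / virtual). The virtual node's embedding part is
  zero; its type bit identifies it. How (or whether) to mark node identity
  is an open design point; the one-hot is the minimal choice that lets
  attention separate the two chains.
* No positional encoding is added. The architecture is therefore exactly
  permutation-invariant over nodes — a property we test — and cannot
  distinguish residue order within a chain. This bounds what it can learn
  (see the benchmark section).

## The classifier

Three rounds of multi-head scaled dot-product attention run over the
complete graph (a skip projection `W_skip · x_i` lets each node retain its
own state, since self-loops are excluded). After each round the node
features pass through GraphNorm — per-graph feature normalization
`γ · (h − α·μ)/σ + β` with a learnable mean-scale α, computed across the
nodes of each graph — and then a ReLU; whether normalization precedes or
follows the nonlinearity is unspecified in common usage, and we adopt
norm-then-activation. The virtual node's final embedding feeds a
one-hidden-layer perceptron (hidden → hidden/2 → 1) with a sigmoid,
yielding an immunogenicity probability in (0, 1).

The network, its hand-derived backward pass, and the Adam optimizer are
implemented directly on NumPy arrays; because the graph is complete,
message passing is computed as dense masked attention over padded
batches, which is far faster on CPU than edge-wise gathers. The backward
pass is verified against central finite differences in the test suite.

Defaults (all overridable via `ModelConfig` or the grid search):
hidden_dim 64, 4 heads, dropout 0.1, learning rate 1e-3, batch 128, up to
50 epochs, early-stopping patience 10 on validation AUC (disable-able for
fixed-epoch runs). Training minimizes binary cross-entropy; no class
reweighting by default. All randomness — initialization, shuffling,
dropout, splits, folds — derives from explicit seeds, so identical seeds
give bitwise-identical runs.

Model selection follows the usual recipe: a stratified 70/30 split
(per-class floor rounding to the training side) for exhaustive grid
search (ties broken toward fewer parameters, then grid order), then
stratified 10-fold cross-validation on the full dataset with out-of-fold
AUC, sensitivity and F1.

## Training-data curation

Assay exports are cleaned in a fixed cascade: (1) drop records without
4-digit HLA resolution (and, by default, non-class-I records); (2) drop
records missing the count fields their outcome requires; (3) keep
negatives only with ≥ 4 experiments, all negative — the evidence rule is
sometimes phrased as "> 4" and sometimes "at least four"; we follow the
latter and expose the threshold as policy; (4) keep positives only with
≥ 1 responding subject; (5) collapse duplicate (peptide, allele) pairs —
concordant duplicates merge, discordant ones are discarded by default
(majority-vote and positive-wins policies are available). The cascade
conserves counts (kept + dropped + rejected = input), is monotone in the
negative-evidence threshold, and leaves already-clean data unchanged.

The similarity search ranks database peptides by global pairwise
alignment score under BLOSUM62 (gap open 11, extend 1), normalized as
`S(q,d) / √(S(q,q) · S(d,d))` so self-similarity is exactly 1; ties keep
database order.

## The screening cascade

For each missense mutation, every 8–14-mer window covering the mutated
residue gives a mutant/wild-type pair (an interior mutation yields
8+9+…+14 = 77 pairs; a terminal one yields 7, with no padding). Each
mutant peptide × allele candidate passes through a pure conjunction of
filters: binding %Rank < 2; DAI = IC50(WT)/IC50(MT) > 1 (strict — equal
binding fails); stability %Rank < 2; processing %Rank < 2; and an
immunogenicity consensus of ≥ 3 votes by default, where score-type tools
vote at score ≥ 0.8 (inclusive) and rank-type tools at %Rank < 2. The
consensus phrase "more than two methods" is genuinely ambiguous between
≥ 2 and ≥ 3; we default to the literal reading (≥ 3) and make `min_votes`
configurable. The wild-type %Rank is recorded but never filtered on.
Because the cascade is a conjunction, its outcome is independent of
filter order, and tightening any threshold can only shrink the survivor
set — both properties are tested.

External binding/stability/processing/immunogenicity tools are not
invoked. The `PredictorSuite` protocol defines the contract a real tool
adapter must satisfy (pure functions; %Ranks in [0, 100]; positive IC50),
and a deterministic hash-based toy suite ships for tests and demos: every
score is a BLAKE2b digest of (seed, channel, peptide, allele) mapped to a
plausible range (IC50 log-uniform on [1, 5·10⁴] nM, ranks uniform on
[0, 100], scores uniform on [0, 1]).

## Metrics

Sensitivity and F1 are computed at an operating threshold of 0.5 by
default (score ≥ threshold calls positive; F1 is 0 when TP = 0). TopK is
the fraction of positives among the K highest-scoring items under a
stable descending sort (ties keep input order); default K ∈ {20, 50, 100}
in the CLI. AUC is the rank-based concordance probability with ties
counted one half, identical to the Mann–Whitney statistic.

## The synthetic benchmark

`gen_labeled_dataset` plants a signal shaped like real class-I
immunogenicity data: the log-odds of a positive label are

    z = effect · (s(p₂) + s(p_L)) / √2 + a(allele) + noise · ε

where `s` is a seeded random projection of the residue embedding
standardized over the 20 residues, p₂ and p_L are the canonical anchor
positions (the most conserved positions in validated epitope
collections), `a` is a per-allele offset and ε is standard normal.
Labels are Bernoulli(sigmoid(z)).

Defaults are fixed at effect 2.0, allele-offset SD 7.0 (offsets centered
over the panel so classes stay near balance), noise 0.5, 8 alleles,
n = 2000. They were chosen so that, by construction, (a) the true
log-odds achieve AUC ≥ 0.95 against the sampled labels, and (b) the best
*permutation-invariant* predictor — which is all this architecture can
be, having no positional encoding — still achieves AUC well above 0.9.
Point (b) matters: a permutation-invariant model observes only the
residue multiset, whose conditional expectation of the anchor term
captures a fraction ≈ 2/L of its variance, so a benchmark dominated by
the anchor term would be unlearnable by design rather than by defect.
Both properties were verified from the generator's analytic ground truth
(n = 20 000, multiple seeds), not by tuning against the trained model.

Benchmark problem sizes used by the tests and the acceptance script —
n = 2000 instances, hidden_dim 32, ≤ 20 epochs for the held-out run,
10 epochs per fold for 10-fold cross-validation, 3 epochs per fold for
the label-shuffled null — are the package's chosen desk-scale conditions;
at these sizes the trained classifier reaches held-out and
cross-validated AUC ≈ 0.92 against a chance-level null of ≈ 0.50.

What the synthetic data does *not* emulate: real binding-affinity
landscapes, allele-frequency structure, assay noise correlated with
laboratory or publication, peptide length distributions of eluted
ligands, or sequence similarity between training and test instances.
Passing benchmarks therefore demonstrate that the pipeline's machinery —
featurization, graph construction, optimization, evaluation — works and
that the architecture can recover a recoverable signal; they say nothing
about predictive performance on real immunopeptidome data, which depends
on training against curated experimental assay collections.

## Known limitations

* Class-I 8–14-mers only; class II records are filtered out (retained
  behind a policy flag for future work).
* The complete-graph attention is O(N²) per layer; fine at N ≤ 49,
  not intended for whole-protein graphs.
* No attention-weight visualization or model interpretation utilities.
* The packaged pseudo-sequence table is synthetic; real use requires
  supplying an allele table in the same TSV format.
* VCF/MAF annotation is out of scope: mutation input is a pre-annotated
  table (gene, position, ref, alt, protein sequence or FASTA reference).
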