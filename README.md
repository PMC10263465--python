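# phlagraph

A toolkit for neoantigen immunogenicity prediction built around a graph
representation of the peptide–HLA complex. It is aimed at computational
immunologists who want a transparent, fully testable implementation of
three pieces of machinery that usually live inside opaque web services:

1. **A graph attention classifier** for peptide–HLA immunogenicity. Each
   amino acid of an 8–14-mer peptide and of the 34-residue HLA
   pseudo-sequence is a node; nodes carry a 20-dimensional embedding
   derived from physicochemical indices (AAindex1 format → missing-value
   removal → median/IQR robust scaling → PCA, top 20 components). The
   graph is fully connected (every ordered pair of distinct nodes is an
   edge) plus one *virtual node* connected to everything. Three layers of
   transformer-style attention message passing with GraphNorm propagate
   information; the virtual node's final embedding passes through a small
   MLP and a sigmoid to give P(immunogenic). Training minimizes binary
   cross-entropy with Adam, with stratified 70/30 grid search and
   stratified 10-fold cross-validation. The network (forward, backward,
   optimizer) is implemented directly in NumPy and verified against
   numerical gradients.

2. **Assay-record curation** turning IEDB-style T-cell assay exports into
   a labeled training set: drop alleles below 4-digit resolution, require
   the evidence counts each label needs (negatives: ≥ 4 experiments, all
   negative; positives: ≥ 1 responding subject), and collapse duplicate
   peptide–HLA instances (discordant duplicates discarded by default).
   Plus a database similarity search by global BLOSUM62 alignment with
   scores normalized so identity = 1.0.

3. **A multi-feature neoantigen screening cascade** from missense driver
   mutations: extract every 8–14-mer mutant/wild-type window pair around
   the mutated residue, then filter by binding %Rank < 2, differential
   agretopicity index DAI = IC50(WT)/IC50(MT) > 1, stability %Rank < 2,
   processing %Rank < 2, and a consensus of immunogenicity tools
   (score ≥ 0.8 or rank < 2; ≥ 3 votes by default). Predictors are
   pluggable through a small contract; a deterministic hash-based toy
   suite ships for testing and demos.

Evaluation metrics (sensitivity, F1, TopK, rank-based AUC) and seeded
generators for every input format round out the package, so the entire
pipeline runs end-to-end with no downloads.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Generate synthetic inputs, curate assay records, train, and predict
(every command is seeded; you will get these exact numbers):

```console
$ phlagraph simulate --what all --seed 7 --n 400 --out inputs
synthetic inputs written to inputs

$ phlagraph curate --in inputs/assays.tsv --out curated.tsv
{
 "n_input": 50,
 "n_instances": 31,
 "dropped_allele": 1,
 "dropped_mhc_class": 1,
 "dropped_missing_counts": 2,
 "dropped_negative_rule": 7,
 "dropped_positive_rule": 4,
 "dropped_conflict": 2,
 "merged_duplicates": 1,
 "n_rejects": 1,
 "rejects": [
  [
   "syn_14",
   "invalid peptide 'ACDX1Z'"
  ]
 ]
}
```

Of 50 assay records, 31 unique labeled peptide–HLA instances survive:
one record lost its allele (2-digit only), one was class II, two lacked
required evidence counts, seven negatives had fewer than four
experiments, four positives had no responding subject, one conflicting
duplicate pair was discarded, one concordant pair merged, and one
malformed row was rejected with a reason.

```console
$ phlagraph train --dataset inputs/dataset.tsv --pseudo inputs/pseudo.tsv \
      --hidden-dim 32 --epochs 10 --seed 7 --model-out model.npz
final train loss 0.4790; best val AUC 0.9490; model -> model.npz

$ printf 'ACDEFGHIK\nLLDYQGMLK\n' > query.pep
$ phlagraph predict --model model.npz --pep query.pep \
      --allele 'HLA-A*01:01' --pseudo inputs/pseudo.tsv
ACDEFGHIK	HLA-A*01:01	0.5937
LLDYQGMLK	HLA-A*01:01	0.4088
```

The model trained on 400 synthetic planted-signal instances separates
held-out data at AUC 0.949; the two query peptides score 0.59 and 0.41 —
probabilities of immunogenicity on this allele under the toy training
distribution.

Screening driver mutations with the toy predictor suite:

```console
$ phlagraph driverneo --mutations inputs/mutations.tsv \
      --alleles 'HLA-A*01:01,HLA-B*01:01' --keep-all --out candidates.csv
{"n_candidates": 1150, "n_errors": 0, "n_passed": 0,
 "per_filter_pass": {"binding": 23, "dai": 569, "stability": 22,
                     "processing": 23, "immunogenicity": 13}}
```

Ten mutations × 2 alleles produce 1150 window candidates; each filter
passes roughly the fraction its threshold implies (%Rank < 2 ≈ 2% of
candidates, DAI > 1 ≈ half), and under the toy suite's independent random
scores no candidate survives the full conjunction — real predictors, whose
channels are strongly correlated for genuine binders, plug in through the
`PredictorSuite` contract.

Database similarity search:

```console
$ printf 'ACDEFGHIK\nACDEFGHIW\nWYWYWYWYW\n' > db.pep
$ phlagraph search --query ACDEFGHIK --db db.pep --top 3
1	ACDEFGHIK	1.0000
2	ACDEFGHIW	0.8047
3	WYWYWYWYW	-0.2865
```

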