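"""Training, tuning and inference for the graph attention classifier.

The classifier scores a peptide-HLA pair for immunogenicity.  Workflow
mirrors the usual supervised recipe for this problem: a stratified 70/30
split for hyperparameter grid search, then 10-fold stratified
cross-validation on the full curated dataset, minimizing binary
cross-entropy with Adam.  All randomness (parameter init, shuffling,
dropout, splits, folds) derives from explicit integer seeds, so every run
is exactly reproducible.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .aaindex import AminoAcidFeatureTable
from .curation import CuratedDataset
from .graph import PseudoSequenceTable, build_phla_graph
from .metrics import LabeledScores, f1, roc_auc, sensitivity


@dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters."""

    n_layers: int = 3
    hidden_dim: int = 64
    n_heads: int = 4
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 50
    early_stop_patience: int = 10
    seed: int = 0
    length_range: tuple[int, int] = (8, 14)

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.hidden_dim, self.n_heads, self.batch_size, self.max_epochs) < 1:
            raise ValueError("dims, heads, batch size and epochs must be positive")
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")


class GraphFeaturizer:
    """Builds padded node-feature batches from (peptide, allele) pairs.

    Featurization of a pair is deterministic, so results are cached.
    """

    def __init__(
        self,
        emb: AminoAcidFeatureTable,
        pseudo_table: PseudoSequenceTable,
        length_range: tuple[int, int] = (8, 14),
    ) -> None:
        self.emb = emb
        self.pseudo_table = pseudo_table
        self.length_range = length_range
        self.in_dim = emb.n_components + 3
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    def features(self, peptide: str, allele: str) -> np.ndarray:
        key = (peptide.upper(), allele)
        if key not in self._cache:
            g = build_phla_graph(
                peptide, allele, self.pseudo_table, self.emb, self.length_range
            )
            self._cache[key] = g.node_features
        return self._cache[key]

    def batch(
        self, pairs: Sequence[tuple[str, str]]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pad a list of pairs into (X, mask, virtual_idx) arrays."""
        feats = [self.features(p, a) for p, a in pairs]
        n_max = max(f.shape[0] for f in feats)
        B = len(feats)
        X = np.zeros((B, n_max, self.in_dim))
        mask = np.zeros((B, n_max))
        virt = np.zeros(B, dtype=int)
        for i, f in enumerate(feats):
            n = f.shape[0]
            X[i, :n] = f
            mask[i, :n] = 1.0
            virt[i] = n - 1  # virtual node is last in node order
        return X, mask, virt


@dataclass
class ImmunoGNNModel:
    """Parameter set plus the configuration that shaped it."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    in_dim: int
    emb_checksum: str = ""
    pseudo_checksum: str = ""

    @classmethod
    def initialize(cls, config: ModelConfig, in_dim: int) -> "ImmunoGNNModel":
        params = nn.init_params(in_dim, config.hidden_dim, config.n_layers, config.seed)
        return cls(params=params, config=config, in_dim=in_dim)

    @property
    def n_parameters(self) -> int:
        return nn.n_parameters(self.params)

    def forward_batch(
        self,
        X: np.ndarray,
        mask: np.ndarray,
        virt: np.ndarray,
        training: bool = False,
        drop_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        if X.shape[-1] != self.in_dim:
            raise ValueError(
                f"feature width {X.shape[-1]} does not match model input "
                f"width {self.in_dim}"
            )
        return nn.forward(
            self.params, X, mask, virt,
            n_layers=self.config.n_layers, n_heads=self.config.n_heads,
            dropout=self.config.dropout, training=training, drop_rng=drop_rng,
        )

    def predict(
        self, pairs: Sequence[tuple[str, str]], featurizer: GraphFeaturizer
    ) -> np.ndarray:
        """Probabilities for a list of (peptide, allele) pairs (eval mode)."""
        if not pairs:
            return np.array([])
        out = np.empty(len(pairs))
        bs = self.config.batch_size
        for start in range(0, len(pairs), bs):
            chunk = pairs[start : start + bs]
            X, mask, virt = featurizer.batch(chunk)
            prob, _ = self.forward_batch(X, mask, virt, training=False)
            out[start : start + len(chunk)] = prob
        return out

    def save(self, path: str | Path) -> None:
        meta = {
            "config": {**self.config.__dict__,
                       "length_range": list(self.config.length_range)},
            "in_dim": self.in_dim,
            "emb_checksum": self.emb_checksum,
            "pseudo_checksum": self.pseudo_checksum,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "ImmunoGNNModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg = meta["config"]
        cfg["length_range"] = tuple(cfg["length_range"])
        params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            params=params, config=ModelConfig(**cfg), in_dim=meta["in_dim"],
            emb_checksum=meta["emb_checksum"],
            pseudo_checksum=meta["pseudo_checksum"],
        )


def embedding_checksum(emb: AminoAcidFeatureTable) -> str:
    mat = np.stack([emb.embedding[r] for r in sorted(emb.embedding)])
    return hashlib.sha256(np.ascontiguousarray(mat).tobytes()).hexdigest()[:16]


def pseudo_checksum(table: PseudoSequenceTable) -> str:
    text = ";".join(f"{a}={s}" for a, s in sorted(table.mapping.items()))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class TrainReport:
    """Losses and metrics collected during training / tuning / CV."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    val_aucs: list[float] = field(default_factory=list)
    fold_metrics: list[dict] = field(default_factory=list)
    fold_assignment: np.ndarray | None = None
    oof_scores: np.ndarray | None = None
    oof_labels: np.ndarray | None = None
    best_config: ModelConfig | None = None
    n_fits: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean([m["auc"] for m in self.fold_metrics]))

    @property
    def sd_auc(self) -> float:
        return float(np.std([m["auc"] for m in self.fold_metrics]))

    def fold_summary(self) -> dict:
        keys = ("auc", "sensitivity", "f1")
        return {
            k: {
                "mean": float(np.mean([m[k] for m in self.fold_metrics])),
                "sd": float(np.std([m[k] for m in self.fold_metrics])),
            }
            for k in keys
        }


def stratified_split(
    dataset: CuratedDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[CuratedDataset, CuratedDataset]:
    """Per-class split: floor(fraction * n_class) to train, rest to validation."""
    labels = np.asarray(dataset.labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("stratified split requires both classes")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        perm = rng.permutation(idx)
        n_train = int(np.floor(train_fraction * idx.size))
        train_idx.extend(perm[:n_train].tolist())
        val_idx.extend(perm[n_train:].tolist())
    train_idx.sort()
    val_idx.sort()
    subset = lambda ids: CuratedDataset([dataset.instances[i] for i in ids])
    return subset(train_idx), subset(val_idx)


def _dataset_pairs(dataset: CuratedDataset) -> list[tuple[str, str]]:
    return [(i.peptide, i.allele) for i in dataset.instances]


def train(
    dataset: CuratedDataset,
    config: ModelConfig,
    emb: AminoAcidFeatureTable,
    pseudo_table: PseudoSequenceTable,
    validation: bool = True,
    early_stop: bool = True,
) -> tuple[ImmunoGNNModel, TrainReport]:
    """Fit the classifier by binary cross-entropy with Adam.

    When ``validation`` is true a stratified 70/30 split is carved out and
    early stopping monitors validation AUC with the configured patience;
    otherwise the model trains on everything for ``max_epochs`` epochs.
    """
    labels = set(dataset.labels)
    if len(dataset) == 0 or len(labels) < 2:
        raise ValueError("training requires a non-empty dataset with both classes")

    featurizer = GraphFeaturizer(emb, pseudo_table, config.length_range)
    if validation:
        train_set, val_set = stratified_split(dataset, 0.7, config.seed)
    else:
        train_set, val_set = dataset, None

    model = ImmunoGNNModel.initialize(config, featurizer.in_dim)
    model.emb_checksum = embedding_checksum(emb)
    model.pseudo_checksum = pseudo_checksum(pseudo_table)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    pairs = _dataset_pairs(train_set)
    y = np.asarray(train_set.labels, dtype=float)
    X_all, mask_all, virt_all = featurizer.batch(pairs)

    report = TrainReport()
    best_auc, best_params, patience_left = -np.inf, None, config.early_stop_patience
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            prob, cache = model.forward_batch(
                X_all[idx], mask_all[idx], virt_all[idx],
                training=True, drop_rng=rng,
            )
            epoch_losses.append(nn.bce_loss(prob, y[idx]))
            grads = nn.backward(model.params, cache, y[idx], config.n_layers)
            opt.step(model.params, grads)
        report.train_losses.append(float(np.mean(epoch_losses)))

        if val_set is not None:
            val_prob = model.predict(_dataset_pairs(val_set), featurizer)
            val_y = np.asarray(val_set.labels, dtype=float)
            report.val_losses.append(nn.bce_loss(val_prob, val_y))
            auc = roc_auc(LabeledScores(val_prob, val_y.astype(int)))
            report.val_aucs.append(auc)
            if auc > best_auc:
                best_auc = auc
                best_params = {k: v.copy() for k, v in model.params.items()}
                patience_left = config.early_stop_patience
            elif early_stop:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if val_set is not None and best_params is not None:
        model.params = best_params
    report.n_fits = 1
    return model, report


def grid_search(
    dataset: CuratedDataset,
    grid: dict[str, list],
    emb: AminoAcidFeatureTable,
    pseudo_table: PseudoSequenceTable,
    base_config: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[ModelConfig, TrainReport]:
    """Exhaustive hyperparameter search on the stratified 70/30 split.

    Every grid combination is trained with the same seed (hence the same
    split); the combination with the highest validation AUC wins.  Ties
    break toward fewer parameters, then grid order.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    base = base_config or ModelConfig()
    names = list(grid)
    report = TrainReport()
    results: list[tuple[float, int, int, ModelConfig]] = []
    for combo_idx, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        cfg = replace(base, **dict(zip(names, combo)), seed=seed)
        model, rep = train(dataset, cfg, emb, pseudo_table, validation=True)
        val_auc = max(rep.val_aucs) if rep.val_aucs else float("nan")
        results.append((val_auc, model.n_parameters, combo_idx, cfg))
        report.n_fits += 1
    results.sort(key=lambda t: (-t[0], t[1], t[2]))
    report.best_config = results[0][3]
    report.fold_metrics = [
        {"auc": auc, "n_parameters": npar, "grid_index": gi}
        for auc, npar, gi, _ in results
    ]
    return report.best_config, report


def cross_validate(
    dataset: CuratedDataset,
    config: ModelConfig,
    emb: AminoAcidFeatureTable,
    pseudo_table: PseudoSequenceTable,
    k: int = 10,
    seed: int = 0,
) -> TrainReport:
    """Stratified k-fold cross-validation with out-of-fold metrics.

    Fold assignment depends only on the seed and dataset order; it is
    returned in the report so runs can be reproduced or resumed.
    """
    labels = np.asarray(dataset.labels)
    pos, neg = int(labels.sum()), int((1 - labels).sum())
    if min(pos, neg) < k:
        raise ValueError(f"each class needs >= {k} members, got {pos}/{neg}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = TrainReport()
    assignment = np.full(len(dataset), -1, dtype=int)
    oof_scores = np.full(len(dataset), np.nan)
    featurizer = GraphFeaturizer(emb, pseudo_table, config.length_range)
    for fold, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(len(dataset)), labels)
    ):
        assignment[test_idx] = fold
        fold_cfg = replace(config, seed=config.seed + fold)
        train_set = CuratedDataset([dataset.instances[i] for i in train_idx])
        model, _ = train(
            train_set, fold_cfg, emb, pseudo_table, validation=False
        )
        test_pairs = [_dataset_pairs(dataset)[i] for i in test_idx]
        prob = model.predict(test_pairs, featurizer)
        oof_scores[test_idx] = prob
        ls = LabeledScores(prob, labels[test_idx])
        report.fold_metrics.append(
            {
                "fold": fold,
                "auc": roc_auc(ls),
                "sensitivity": sensitivity(ls),
                "f1": f1(ls),
                "n_test": int(test_idx.size),
            }
        )
        report.n_fits += 1
    report.fold_assignment = assignment
    report.oof_scores = oof_scores
    report.oof_labels = labels
    return report


@dataclass
class BatchPredictionError:
    index: int
    peptide: str
    allele: str
    message: str


def predict_batch(
    pairs: Sequence[tuple[str, str]],
    model: ImmunoGNNModel,
    emb: AminoAcidFeatureTable,
    pseudo_table: PseudoSequenceTable,
    on_error: str = "raise",
) -> tuple[list[float | None], list[BatchPredictionError]]:
    """Score (peptide, allele) pairs, order-preserving.

    With ``on_error='skip'``, rows that cannot be featurized (unknown
    allele, bad length) yield ``None`` plus an error record instead of
    aborting the batch.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"unknown error policy {on_error!r}")
    featurizer = GraphFeaturizer(emb, pseudo_table, model.config.length_range)
    scores: list[float | None] = [None] * len(pairs)
    errors: list[BatchPredictionError] = []
    good: list[int] = []
    for i, (pep, allele) in enumerate(pairs):
        try:
            featurizer.features(pep, allele)
            good.append(i)
        except (ValueError, KeyError) as exc:
            if on_error == "raise":
                raise
            errors.append(BatchPredictionError(i, pep, allele, str(exc)))
    if good:
        prob = model.predict([pairs[i] for i in good], featurizer)
        for i, p in zip(good, prob):
            scores[i] = float(p)
    return scores, errors
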