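"""Training orchestration: splits, grid search, CV, batch prediction."""

import numpy as np
import pytest

from phlagraph.curation import CuratedDataset, Instance
from phlagraph.model import (
    GraphFeaturizer,
    ImmunoGNNModel,
    ModelConfig,
    cross_validate,
    grid_search,
    predict_batch,
    stratified_split,
    train,
)
from phlagraph.synth import SyntheticConfig, gen_labeled_dataset


def make_dataset(n_pos, n_neg, alleles, seed=0):
    rng = np.random.default_rng(seed)
    residues = list("ACDEFGHIKLMNPQRSTVWY")
    insts = []
    for i in range(n_pos + n_neg):
        pep = "".join(rng.choice(residues, size=9))
        insts.append(
            Instance(pep, alleles[i % len(alleles)], int(i < n_pos))
        )
    return CuratedDataset(insts)


@pytest.fixture(scope="module")
def small_planted(embedding, pseudo_table):
    cfg = SyntheticConfig(seed=11, n_peptides=300)
    return gen_labeled_dataset(cfg, embedding, pseudo_table)[0]


FAST = dict(hidden_dim=16, n_heads=2, max_epochs=3, batch_size=64)


class TestStratifiedSplit:
    def test_balanced_counts(self, pseudo_table):
        ds = make_dataset(100, 100, pseudo_table.alleles)
        tr, va = stratified_split(ds, 0.7, seed=0)
        assert tr.class_counts() == (70, 70)
        assert va.class_counts() == (30, 30)

    def test_floor_rounding(self, pseudo_table):
        ds = make_dataset(7, 3, pseudo_table.alleles)
        tr, va = stratified_split(ds, 0.7, seed=0)
        assert tr.class_counts() == (4, 2)
        assert va.class_counts() == (3, 1)

    def test_disjoint_and_exhaustive(self, pseudo_table):
        ds = make_dataset(20, 30, pseudo_table.alleles)
        tr, va = stratified_split(ds, 0.7, seed=1)
        tr_keys = {(i.peptide, i.allele) for i in tr.instances}
        va_keys = {(i.peptide, i.allele) for i in va.instances}
        assert not tr_keys & va_keys
        assert len(tr_keys | va_keys) == 50

    def test_seeding_contract(self, pseudo_table):
        ds = make_dataset(20, 20, pseudo_table.alleles)
        a1 = stratified_split(ds, 0.7, seed=5)[0]
        a2 = stratified_split(ds, 0.7, seed=5)[0]
        b = stratified_split(ds, 0.7, seed=6)[0]
        key = lambda d: [(i.peptide, i.allele) for i in d.instances]
        assert key(a1) == key(a2)
        assert key(a1) != key(b)
        assert b.class_counts() == a1.class_counts()

    def test_tiny_class_errors(self, pseudo_table):
        ds = make_dataset(1, 10, pseudo_table.alleles)
        with pytest.raises(ValueError):
            stratified_split(ds, 0.7, seed=0)


class TestTrain:
    def test_loss_decreases_on_planted_data(
        self, small_planted, embedding, pseudo_table
    ):
        cfg = ModelConfig(hidden_dim=16, n_heads=2, max_epochs=5, seed=0)
        _, report = train(
            small_planted, cfg, embedding, pseudo_table, validation=False
        )
        assert report.train_losses[-1] < report.train_losses[0]

    def test_seeded_determinism(self, small_planted, embedding, pseudo_table):
        cfg = ModelConfig(seed=3, **FAST)
        _, r1 = train(small_planted, cfg, embedding, pseudo_table)
        _, r2 = train(small_planted, cfg, embedding, pseudo_table)
        assert abs(r1.train_losses[-1] - r2.train_losses[-1]) < 1e-6

    def test_single_class_errors(self, pseudo_table, embedding):
        ds = make_dataset(10, 0, pseudo_table.alleles)
        with pytest.raises(ValueError):
            train(ds, ModelConfig(**FAST), embedding, pseudo_table)

    def test_early_stopping_restores_best(
        self, small_planted, embedding, pseudo_table
    ):
        cfg = ModelConfig(seed=0, hidden_dim=16, n_heads=2, max_epochs=6,
                          early_stop_patience=2)
        model, report = train(small_planted, cfg, embedding, pseudo_table)
        assert len(report.val_aucs) <= cfg.max_epochs
        assert max(report.val_aucs) >= report.val_aucs[-1] - 1e-12


class TestGridSearch:
    def test_single_point_grid_identity(
        self, small_planted, embedding, pseudo_table
    ):
        best, report = grid_search(
            small_planted, {"hidden_dim": [16]}, embedding, pseudo_table,
            base_config=ModelConfig(**FAST), seed=0,
        )
        assert best.hidden_dim == 16
        assert report.n_fits == 1

    def test_fit_count_is_grid_product(
        self, small_planted, embedding, pseudo_table
    ):
        _, report = grid_search(
            small_planted,
            {"hidden_dim": [8, 16], "learning_rate": [1e-3, 1e-2]},
            embedding, pseudo_table,
            base_config=ModelConfig(n_heads=2, max_epochs=2, batch_size=64),
            seed=0,
        )
        assert report.n_fits == 4

    def test_degenerate_config_loses(
        self, small_planted, embedding, pseudo_table
    ):
        # a 2-unit single-head model cannot match a 32-unit one on planted data
        best, _ = grid_search(
            small_planted, {"hidden_dim": [2, 32]}, embedding, pseudo_table,
            base_config=ModelConfig(n_heads=1, max_epochs=8, batch_size=64),
            seed=0,
        )
        assert best.hidden_dim == 32

    def test_empty_grid_errors(self, small_planted, embedding, pseudo_table):
        with pytest.raises(ValueError):
            grid_search(small_planted, {}, embedding, pseudo_table)


class TestCrossValidate:
    def test_stratified_fold_counts(self, embedding, pseudo_table):
        ds = make_dataset(100, 100, pseudo_table.alleles)
        report = cross_validate(
            ds, ModelConfig(hidden_dim=8, n_heads=1, max_epochs=1),
            embedding, pseudo_table, k=10, seed=0,
        )
        assert len(report.fold_metrics) == 10
        for fold in range(10):
            idx = report.fold_assignment == fold
            assert idx.sum() == 20
            assert report.oof_labels[idx].sum() == 10  # 10 pos + 10 neg held out

    def test_fold_assignment_depends_only_on_seed(
        self, embedding, pseudo_table
    ):
        ds = make_dataset(30, 30, pseudo_table.alleles)
        cfg = ModelConfig(hidden_dim=8, n_heads=1, max_epochs=1)
        r1 = cross_validate(ds, cfg, embedding, pseudo_table, k=3, seed=4)
        r2 = cross_validate(ds, cfg, embedding, pseudo_table, k=3, seed=4)
        r3 = cross_validate(ds, cfg, embedding, pseudo_table, k=3, seed=5)
        assert np.array_equal(r1.fold_assignment, r2.fold_assignment)
        assert not np.array_equal(r1.fold_assignment, r3.fold_assignment)

    def test_small_class_errors(self, embedding, pseudo_table):
        ds = make_dataset(5, 50, pseudo_table.alleles)
        with pytest.raises(ValueError):
            cross_validate(ds, ModelConfig(**FAST), embedding, pseudo_table,
                           k=10, seed=0)


@pytest.fixture(scope="module")
def model(embedding):
    return ImmunoGNNModel.initialize(
        ModelConfig(hidden_dim=16, n_heads=2, seed=0),
        embedding.n_components + 3,
    )


class TestPredictBatch:

    def test_batch_of_one_equals_forward(self, model, embedding, pseudo_table):
        featurizer = GraphFeaturizer(embedding, pseudo_table)
        pair = ("ACDEFGHIK", pseudo_table.alleles[0])
        scores, errors = predict_batch([pair], model, embedding, pseudo_table)
        direct = model.predict([pair], featurizer)
        assert not errors
        assert abs(scores[0] - direct[0]) < 1e-12

    def test_batch_equals_loop_over_singles(
        self, model, embedding, pseudo_table
    ):
        rng = np.random.default_rng(0)
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        pairs = [
            ("".join(rng.choice(residues, size=int(rng.integers(8, 15)))),
             pseudo_table.alleles[i % 3])
            for i in range(12)
        ]
        batch_scores, _ = predict_batch(pairs, model, embedding, pseudo_table)
        single_scores = [
            predict_batch([p], model, embedding, pseudo_table)[0][0]
            for p in pairs
        ]
        np.testing.assert_allclose(batch_scores, single_scores, atol=1e-6)

    def test_skip_policy_isolates_bad_rows(self, model, embedding, pseudo_table):
        pairs = [
            ("ACDEFGHIK", pseudo_table.alleles[0]),
            ("ACDEFGHIK", "HLA-A*99:99"),  # unknown allele
            ("ACDEFGHIK", pseudo_table.alleles[1]),
        ]
        scores, errors = predict_batch(
            pairs, model, embedding, pseudo_table, on_error="skip"
        )
        assert scores[1] is None and scores[0] is not None and scores[2] is not None
        assert len(errors) == 1 and errors[0].index == 1

    def test_raise_policy(self, model, embedding, pseudo_table):
        with pytest.raises(KeyError):
            predict_batch(
                [("ACDEFGHIK", "HLA-A*99:99")], model, embedding, pseudo_table
            )

    def test_empty_input(self, model, embedding, pseudo_table):
        scores, errors = predict_batch([], model, embedding, pseudo_table)
        assert scores == [] and errors == []


def test_checkpoint_roundtrip(tmp_path, embedding, pseudo_table):
    model = ImmunoGNNModel.initialize(
        ModelConfig(hidden_dim=16, n_heads=2, seed=2), embedding.n_components + 3
    )
    featurizer = GraphFeaturizer(embedding, pseudo_table)
    pairs = [("ACDEFGHIK", pseudo_table.alleles[0])]
    before = model.predict(pairs, featurizer)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = ImmunoGNNModel.load(path)
    after = loaded.predict(pairs, featurizer)
    np.testing.assert_array_equal(before, after)
    assert loaded.config == model.config
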