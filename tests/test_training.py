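"""Fold plans, prior sampling, halving search, patience semantics, recovery."""

import numpy as np
import pytest
from scipy import stats

import scregmotif.training as training
from scregmotif.network import ModelConfig, ModelParams, forward, im2col
from scregmotif.training import (
    HyperPriors,
    evaluate,
    hyperparameter_search,
    make_cv_plan,
    sample_hyperparams,
    train_model,
)


class TestCVPlan:
    def test_partition_arithmetic(self):
        plan = make_cv_plan(100, 10, np.random.default_rng(0))
        tests = [fold["outer_test"] for fold in plan.folds]
        assert all(len(t) == 10 for t in tests)
        union = np.concatenate(tests)
        assert len(union) == 100 and len(np.unique(union)) == 100

    def test_inner_split_is_80_20(self):
        plan = make_cv_plan(100, 10, np.random.default_rng(0))
        for fold in plan.folds:
            assert len(fold["inner_train"]) == 72
            assert len(fold["inner_val"]) == 18
            combined = np.concatenate([fold["outer_test"], fold["inner_train"],
                                       fold["inner_val"]])
            assert len(np.unique(combined)) == 100

    def test_seeded_determinism(self):
        a = make_cv_plan(57, 5, np.random.default_rng(4))
        b = make_cv_plan(57, 5, np.random.default_rng(4))
        for fa, fb in zip(a.folds, b.folds):
            for key in fa:
                assert np.array_equal(fa[key], fb[key])

    def test_too_few_sequences_errors(self):
        with pytest.raises(ValueError, match="smaller"):
            make_cv_plan(5, 10, np.random.default_rng(0))


class TestHyperSampling:
    def test_draws_respect_bounds_and_median(self):
        priors = HyperPriors()
        rng = np.random.default_rng(0)
        draws = [sample_hyperparams(priors, rng) for _ in range(10_000)]
        lrs = np.array([d["lr"] for d in draws])
        assert lrs.min() >= 5e-4 and lrs.max() <= 5e-2
        geo_mean = np.sqrt(5e-4 * 5e-2)
        assert abs(np.median(lrs) - geo_mean) / geo_mean < 0.10
        for key, (lo, hi) in (("sigma_motifs", priors.sigma_motifs),
                              ("sigma_net", priors.sigma_net)):
            vals = np.array([d[key] for d in draws])
            assert vals.min() >= lo and vals.max() <= hi

    def test_batch_sizes_uniform(self):
        priors = HyperPriors()
        rng = np.random.default_rng(1)
        draws = [sample_hyperparams(priors, rng)["batch_size"] for _ in range(10_000)]
        counts = [draws.count(b) for b in priors.batch_sizes]
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            HyperPriors(lr=(0.0, 1.0))


def _random_data(rng, n=40, L=20, m=4, p=2):
    from scregmotif.data_io import SequenceSet

    seqs = SequenceSet.from_sequences(
        [f"s{i}" for i in range(n)],
        ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)])
    return seqs, im2col(seqs.onehot.astype(float), m)


class TestHyperparameterSearch:
    def test_single_candidate_returned_unchanged(self):
        priors = HyperPriors(num_calibrations=1)
        expected = sample_hyperparams(HyperPriors(), np.random.default_rng(0))
        got = hyperparameter_search(None, None, None, None, priors, np.random.default_rng(0))
        assert got == expected

    def test_selects_near_optimal_lr_on_monotone_surface(self, monkeypatch):
        """With validation MSE a known monotone function of lr, the search
        must return a candidate in the top decile of its own sampled lrs."""
        sampled = []
        real_sample = training.sample_hyperparams

        def record_sample(priors, rng):
            hp = real_sample(priors, rng)
            sampled.append(hp["lr"])
            return hp

        def fake_train(cols, targets, fold, mc, hp, epochs, rng, patience=None):
            class Stub:
                best_val_mse = hp["lr"]  # lower lr strictly better
            return Stub()

        monkeypatch.setattr(training, "sample_hyperparams", record_sample)
        monkeypatch.setattr(training, "train_model", fake_train)
        priors = HyperPriors(num_calibrations=30)
        best = hyperparameter_search(None, None, None, None, priors, np.random.default_rng(3))
        assert best["lr"] <= np.quantile(sampled, 0.1)

    def test_budget_strictly_below_exhaustive(self, monkeypatch):
        trained_epochs = []

        def fake_train(cols, targets, fold, mc, hp, epochs, rng, patience=None):
            trained_epochs.append(epochs)

            class Stub:
                best_val_mse = hp["lr"]
            return Stub()

        monkeypatch.setattr(training, "train_model", fake_train)
        priors = HyperPriors(num_calibrations=27, epochs=36)
        hyperparameter_search(None, None, None, None, priors, np.random.default_rng(0))
        assert sum(trained_epochs) < 27 * 36


class TestTrainModel:
    def test_patience_one_stops_on_first_non_improvement(self, monkeypatch):
        """Validation MSE sequence [3, 2, 2.5] must stop after the third
        epoch and return the epoch-2 parameters."""
        rng = np.random.default_rng(0)
        seqs, cols = _random_data(rng)
        targets = rng.normal(size=(len(seqs), 2))
        fold = {"inner_train": np.arange(30), "inner_val": np.arange(30, 40),
                "outer_test": np.array([], dtype=int)}
        scripted = iter([3.0, 2.0, 2.5, 1.0])
        recorded_preds = []

        def scripted_mse(pred, target):
            recorded_preds.append(np.asarray(pred).copy())
            return next(scripted)

        monkeypatch.setattr(training, "mse_loss", scripted_mse)
        hp = {"lr": 1e-3, "sigma_motifs": 1e-4, "sigma_net": 1e-3, "batch_size": 16}
        mc = ModelConfig(d=3, m=4, p=2, L=20)
        ckpt = train_model(cols, targets, fold, mc, hp, epochs=10, rng=rng)
        assert ckpt.history == [3.0, 2.0, 2.5]
        assert ckpt.best_val_mse == 2.0
        # returned params are the epoch-2 snapshot: they reproduce epoch-2 preds
        val_pred, _ = forward(ckpt.params, None, cols=cols[fold["inner_val"]])
        assert np.allclose(val_pred, recorded_preds[1])

    def test_same_seed_identical_checkpoint(self):
        rng_data = np.random.default_rng(1)
        seqs, cols = _random_data(rng_data)
        targets = rng_data.normal(size=(len(seqs), 2))
        fold = {"inner_train": np.arange(30), "inner_val": np.arange(30, 40),
                "outer_test": np.array([], dtype=int)}
        hp = {"lr": 1e-2, "sigma_motifs": 1e-4, "sigma_net": 1e-3, "batch_size": 16}
        mc = ModelConfig(d=3, m=4, p=2, L=20)
        a = train_model(cols, targets, fold, mc, hp, epochs=5, rng=np.random.default_rng(9))
        b = train_model(cols, targets, fold, mc, hp, epochs=5, rng=np.random.default_rng(9))
        assert np.array_equal(a.params.conv_filters, b.params.conv_filters)
        assert a.history == b.history

    def test_recovers_planted_model(self):
        """Noise-free targets fully determined by deterministic planted
        motifs: the fit should explain >90% of held-out variance."""
        from scregmotif.synthetic_data import (
            DEFAULT_CONSENSI,
            SimulationConfig,
            simulate_dataset,
            consensus_ppm,
        )

        cfg = SimulationConfig(
            n_sequences=500, L=100, noise_sd=0.0,
            motif_ppms=[consensus_ppm(c, dominant=1.0) for c in DEFAULT_CONSENSI],
            rng_seed=7)
        ds = simulate_dataset(cfg)
        targets = ds.pooled.values
        cols = im2col(ds.sequences.onehot.astype(float), 12)
        plan = make_cv_plan(500, 5, np.random.default_rng(0))
        hp = {"lr": 2e-2, "sigma_motifs": 1e-4, "sigma_net": 1e-3, "batch_size": 64}
        mc = ModelConfig(d=20, m=12, p=targets.shape[1], L=100)
        ckpt = train_model(cols, targets, plan.folds[0], mc, hp, epochs=150,
                           rng=np.random.default_rng(1), patience=None)
        results = evaluate(ckpt, ds.sequences, targets, np.random.default_rng(5))
        assert results["r2"] > 0.9

    def test_validation_mse_improves_across_seeds(self):
        """Optimization makes progress: final <= initial val MSE in >=9/10 seeds."""
        rng = np.random.default_rng(3)
        seqs, cols = _random_data(rng, n=100, L=30, m=4, p=3)
        targets = rng.normal(size=(100, 3)) + 1.0
        fold = {"inner_train": np.arange(80), "inner_val": np.arange(80, 100),
                "outer_test": np.array([], dtype=int)}
        hp = {"lr": 5e-3, "sigma_motifs": 1e-4, "sigma_net": 1e-3, "batch_size": 32}
        mc = ModelConfig(d=4, m=4, p=3, L=30)
        wins = sum(
            (lambda h: h[-1] <= h[0])(
                train_model(cols, targets, fold, mc, hp, epochs=8,
                            rng=np.random.default_rng(seed), patience=None).history)
            for seed in range(10))
        assert wins >= 9

    def test_nan_loss_aborts_with_diagnostic(self):
        rng = np.random.default_rng(0)
        seqs, cols = _random_data(rng)
        targets = rng.normal(size=(40, 2))
        fold = {"inner_train": np.arange(30), "inner_val": np.arange(30, 40),
                "outer_test": np.array([], dtype=int)}
        # an absurd learning rate overflows the squared residuals to inf
        hp = {"lr": 1e200, "sigma_motifs": 1e-4, "sigma_net": 1e-3, "batch_size": 16}
        mc = ModelConfig(d=3, m=4, p=2, L=20)
        with pytest.raises(FloatingPointError, match="learning rate"):
            train_model(cols, targets, fold, mc, hp, epochs=5, rng=rng)


class TestEvaluate:
    def test_perfect_predictions_give_r2_one(self):
        rng = np.random.default_rng(4)
        seqs, _ = _random_data(rng, n=30, L=25, m=5, p=3)
        planted = ModelParams(rng.normal(0, 0.4, (4, 5, 4)),
                              rng.normal(0, 0.5, (4, 3)), rng.normal(0, 0.1, 3))
        targets, _ = forward(planted, seqs.onehot.astype(float))
        from scregmotif.network import Checkpoint

        ckpt = Checkpoint(params=planted, config=ModelConfig(d=4, m=5, p=3, L=25),
                          train_ids=np.arange(20), val_ids=np.arange(20, 25),
                          test_ids=np.arange(25, 30), best_val_mse=0.0)
        results = evaluate(ckpt, seqs, targets, np.random.default_rng(0))
        assert results["r2"] == pytest.approx(1.0)

    def test_no_leakage_between_splits(self, flagship):
        for ckpt in flagship["ensemble"].checkpoints:
            assert len(np.intersect1d(ckpt.train_ids, ckpt.test_ids)) == 0
            assert len(np.intersect1d(ckpt.train_ids, ckpt.val_ids)) == 0
            assert len(np.intersect1d(ckpt.val_ids, ckpt.test_ids)) == 0
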