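import dataclasses

import numpy as np
import pytest

from essprot import evaluation as ev
from essprot import model_core as mc


class TestTrainingConfig:
    def test_defaults_match_training_protocol(self):
        cfg = mc.TrainingConfig()
        assert (cfg.epochs, cfg.batch_size, cfg.learning_rate) == (20, 64, 0.001)
        assert cfg.optimizer == "rmsprop"
        assert cfg.split_fractions == (0.6, 0.2, 0.2)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            mc.TrainingConfig.from_dict({"epochs": 5, "bogus": 1})

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            mc.TrainingConfig(split_fractions=(0.5, 0.4, 0.2))

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("epochs: 3\nimbalance_mode: class_weight\n")
        cfg = mc.TrainingConfig.from_yaml(path)
        assert cfg.epochs == 3 and cfg.imbalance_mode == "class_weight"


def _toy_bundle(n=100, seed=0, K=8, d=6, T=4):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.3).astype(int)
    return mc.FeatureBundle(
        proteins=[f"P{i}" for i in range(n)],
        expression=rng.normal(size=(n, 2, 3, T)),
        localization=rng.random((n, K)),
        embedding=rng.normal(size=(n, d)),
        labels=y,
    )


class TestSplitDataset:
    def test_sizes_60_20_20(self):
        train, val, test = mc.split_dataset(_toy_bundle(100))
        assert (len(train), len(val), len(test)) == (60, 20, 20)

    def test_same_seed_identical_partitions(self):
        bundle = _toy_bundle(50)
        a = mc.split_dataset(bundle, seed=3)
        b = mc.split_dataset(bundle, seed=3)
        for x, y in zip(a, b):
            assert x.proteins == y.proteins

    def test_partitions_disjoint_and_exhaustive(self):
        bundle = _toy_bundle(47)
        train, val, test = mc.split_dataset(bundle, seed=1)
        ids = train.proteins + val.proteins + test.proteins
        assert sorted(ids) == sorted(bundle.proteins)
        assert len(set(ids)) == len(ids)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            mc.split_dataset(_toy_bundle(10), fractions=(0.5, 0.5, 0.0))


class TestBalancedEpochSample:
    def test_exact_one_to_one_ratio(self):
        y = np.array([1] * 10 + [0] * 40)
        idx = mc.balanced_epoch_sample(y, seed=0, epoch_index=0)
        assert len(idx) == 20
        assert y[idx].sum() == 10

    def test_fresh_negatives_each_epoch(self):
        y = np.array([1] * 10 + [0] * 200)
        a = mc.balanced_epoch_sample(y, seed=0, epoch_index=0)
        b = mc.balanced_epoch_sample(y, seed=0, epoch_index=1)
        assert set(a[y[a] == 0]) != set(b[y[b] == 0])

    def test_more_positives_than_negatives_rejected(self):
        y = np.array([1] * 5 + [0] * 3)
        with pytest.raises(ValueError):
            mc.balanced_epoch_sample(y, seed=0, epoch_index=0)

    def test_never_selected_fraction_matches_closed_form(self):
        # moderate sizes: Monte-Carlo across several independent runs
        E, NE, n_epochs, runs = 60, 240, 20, 50
        y = np.array([1] * E + [0] * NE)
        expected = mc.non_selection_probability(E, NE, n_epochs, "balanced")
        never = 0
        for run in range(runs):
            seen = np.zeros(E + NE, bool)
            for epoch in range(n_epochs):
                seen[mc.balanced_epoch_sample(y, seed=run, epoch_index=epoch)] = True
            never += (~seen[E:]).sum()
        frac = never / (NE * runs)
        se = np.sqrt(expected * (1 - expected) / (NE * runs))
        assert abs(frac - expected) < 3 * se + 1e-4

    def test_union_of_epoch_samples_covers_most_negatives(self):
        E, NE, n_epochs = 60, 240, 20
        y = np.array([1] * E + [0] * NE)
        seen = np.zeros(E + NE, bool)
        for epoch in range(n_epochs):
            seen[mc.balanced_epoch_sample(y, seed=4, epoch_index=epoch)] = True
        p1 = mc.non_selection_probability(E, NE, n_epochs, "balanced")
        coverage = seen[E:].mean()
        se = np.sqrt(p1 * (1 - p1) / NE)
        assert coverage >= 1 - p1 - 3 * se


class TestNonSelectionProbability:
    def test_balanced_closed_form_matches_reported_value(self):
        assert mc.non_selection_probability(1132, 4856, 20, "balanced") == pytest.approx(
            0.00496, abs=2e-5
        )

    def test_raw_closed_form_matches_reported_value(self):
        assert mc.non_selection_probability(1132, 4856, 20, "raw") == pytest.approx(
            7.5e-5, rel=0.02
        )

    def test_zero_iterations_is_certain_survival(self):
        assert mc.non_selection_probability(5, 10, 0, "balanced") == 1.0
        assert mc.non_selection_probability(5, 10, 0, "raw") == 1.0

    def test_balanced_requires_enough_negatives(self):
        with pytest.raises(ValueError):
            mc.non_selection_probability(10, 5, 3, "balanced")


class TestModel:
    def _model(self, branches=mc.BRANCHES, seed=0, filters=8):
        cfg = mc.TrainingConfig(seed=seed, conv_filters=filters)
        return mc.build_model(cfg, (2, 3, 4), 8, 6, branches=branches), cfg

    def test_forward_yields_probabilities(self):
        model, _ = self._model()
        bundle = _toy_bundle(10)
        prob = model.forward(bundle.expression, bundle.localization, bundle.embedding)
        assert prob.shape == (10,)
        assert ((prob >= 0) & (prob <= 1)).all()

    def test_embedding_only_ablation_still_valid(self):
        model, _ = self._model(branches=("embedding",))
        assert model.head_hidden.W.shape == (16, 16)
        bundle = _toy_bundle(4)
        prob = model.forward(bundle.expression, bundle.localization, bundle.embedding)
        assert prob.shape == (4,)

    def test_all_branches_disabled_rejected(self):
        with pytest.raises(ValueError):
            self._model(branches=())

    def test_parameter_count_matches_closed_form(self):
        model, _ = self._model(filters=8)
        F, K, d, n_cond = 8, 8, 6, 2
        expr = n_cond * (3 * 3 * F + F) + n_cond * 2 * F + (n_cond * F * F + F) + (F * 16 + 16)
        loc = (K * 64 + 64) + (64 * 64 + 64) + 2 * 64 + (64 * 16 + 16)
        emb = (d * 64 + 64) + (64 * 16 + 16)
        head = (48 * 16 + 16) + (16 * 1 + 1)
        assert model.parameter_count() == expr + loc + emb + head

    def test_model_gradient_matches_numerical(self):
        """End-to-end backprop check through all three branches and the head."""
        model, _ = self._model(filters=2)
        bundle = _toy_bundle(6, seed=3)
        y = bundle.labels.astype(float)
        w = np.ones(6)

        def loss():
            p = np.clip(
                model.forward(
                    bundle.expression, bundle.localization, bundle.embedding, train=True
                ),
                1e-12,
                1 - 1e-12,
            )
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        loss()
        model.backward(y, w)
        grads = [g.copy() for g in model.grads]
        eps = 1e-6
        rng = np.random.default_rng(0)
        for param, grad in zip(model.params, grads):
            flat_idx = rng.integers(param.size, size=min(3, param.size))
            for i in flat_idx:
                idx = np.unravel_index(i, param.shape)
                orig = param[idx]
                param[idx] = orig + eps
                up = loss()
                param[idx] = orig - eps
                down = loss()
                param[idx] = orig
                assert grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-4)

    def test_save_load_round_trip(self, tmp_path):
        model, cfg = self._model(seed=5)
        bundle = _toy_bundle(30, seed=5)
        mc.train_model(model, bundle, dataclasses.replace(cfg, epochs=2))
        path = tmp_path / "model.npz"
        model.save(path)
        clone = mc.ThreeBranchModel.load(path)
        p1, _ = mc.predict(model, bundle)
        p2, _ = mc.predict(clone, bundle)
        np.testing.assert_array_equal(p1, p2)


class TestTraining:
    def test_loss_decreases_on_easy_planted_signal(self):
        rng = np.random.default_rng(8)
        n = 300
        y = (rng.random(n) < 0.3).astype(int)
        # plant a strong linear signal in the localization block
        loc = rng.random((n, 8))
        loc[y == 1, 0] += 2.0
        bundle = mc.FeatureBundle(
            proteins=[f"P{i}" for i in range(n)],
            expression=rng.normal(size=(n, 2, 3, 4)),
            localization=loc,
            embedding=rng.normal(size=(n, 6)),
            labels=y,
        )
        cfg = mc.TrainingConfig(seed=1, epochs=5, conv_filters=4)
        model = mc.build_model(cfg, (2, 3, 4), 8, 6)
        _, history = mc.train_model(model, bundle, cfg)
        losses = [h["train_loss"] for h in history]
        assert losses[1] < losses[0] and losses[2] < losses[1]

    def test_sampling_mode_balances_every_epoch(self):
        y = np.array([1] * 30 + [0] * 170)
        for epoch in range(5):
            idx = mc._epoch_indices(y, "sampling", seed=0, epoch=epoch)
            assert y[idx].sum() * 2 == len(idx)

    def test_raw_mode_uses_twice_positive_count(self):
        y = np.array([1] * 30 + [0] * 170)
        idx = mc._epoch_indices(y, "raw", seed=0, epoch=0)
        assert len(idx) == 60

    def test_class_weight_one_equals_unweighted_gradients(self):
        model, _ = self._make_small()
        bundle = _toy_bundle(16, seed=2)
        y = bundle.labels.astype(float)
        model.forward(bundle.expression, bundle.localization, bundle.embedding, train=True)
        model.backward(y, np.ones(16))
        unweighted = [g.copy() for g in model.grads]
        model.forward(bundle.expression, bundle.localization, bundle.embedding, train=True)
        model.backward(y, np.where(y == 1, 1.0, 1.0))
        for a, b in zip(unweighted, model.grads):
            np.testing.assert_array_equal(a, b)

    def _make_small(self):
        cfg = mc.TrainingConfig(seed=0, conv_filters=4)
        return mc.build_model(cfg, (2, 3, 4), 8, 6), cfg

    def test_single_class_training_split_rejected(self):
        bundle = _toy_bundle(30)
        bundle.labels[:] = 0
        model, cfg = self._make_small()
        with pytest.raises(ValueError, match="single class"):
            mc.train_model(model, bundle, cfg)

    def test_threshold_boundary_is_positive(self):
        model, _ = self._make_small()
        bundle = _toy_bundle(5)
        prob, hard = mc.predict(model, bundle, threshold=0.5)
        np.testing.assert_array_equal(hard, (prob >= 0.5).astype(int))

    def test_prediction_deterministic_in_inference(self):
        model, _ = self._make_small()
        bundle = _toy_bundle(12)
        p1, _ = mc.predict(model, bundle)
        p2, _ = mc.predict(model, bundle)
        np.testing.assert_array_equal(p1, p2)
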