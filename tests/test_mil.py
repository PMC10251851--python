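"""Gated attention pooling, the smooth top-1 SVM loss, training with early
stopping, and patient-level cross-validation."""

import numpy as np
import pytest
from scipy.special import logsumexp

from slideattn.bags import FeatureBag
from slideattn.mil import (AttentionParams, TrainConfig, assign_folds,
                           attention_pool, crossvalidate, predict,
                           smooth_top1_svm_loss, train)


def random_params(rng, L=4, d=5):
    return AttentionParams(v=rng.standard_normal((L, d)),
                           u=rng.standard_normal((L, d)),
                           w=rng.standard_normal(L))


class TestAttentionPool:
    def test_singleton_bag(self, rng):
        h = rng.standard_normal((1, 5))
        z, a = attention_pool(h, random_params(rng))
        np.testing.assert_allclose(a, [1.0])
        np.testing.assert_allclose(z, h[0])

    def test_identical_instances_uniform_attention(self, rng):
        h = np.tile(rng.standard_normal(5), (7, 1))
        _, a = attention_pool(h, random_params(rng))
        np.testing.assert_allclose(a, np.full(7, 1 / 7), atol=1e-12)

    def test_matches_direct_formula(self, rng):
        h = rng.standard_normal((3, 5))
        p = random_params(rng)
        z, a = attention_pool(h, p)
        # direct evaluation, one instance at a time
        e = []
        for k in range(3):
            t = np.tanh(p.v @ h[k])
            g = 1 / (1 + np.exp(-p.u @ h[k]))
            e.append(float(p.w @ (t * g)))
        e = np.asarray(e)
        a_direct = np.exp(e - logsumexp(e))
        np.testing.assert_allclose(a, a_direct, rtol=1e-12)
        np.testing.assert_allclose(z, sum(a_direct[k] * h[k] for k in range(3)),
                                   rtol=1e-12)

    def test_permutation_behaviour(self, rng):
        h = rng.standard_normal((6, 5))
        p = random_params(rng)
        perm = rng.permutation(6)
        z1, a1 = attention_pool(h, p)
        z2, a2 = attention_pool(h[perm], p)
        np.testing.assert_allclose(a2, a1[perm], rtol=1e-12)
        np.testing.assert_allclose(z1, z2, rtol=1e-9)

    def test_attention_sums_to_one(self, rng):
        for n in (1, 2, 17):
            _, a = attention_pool(rng.standard_normal((n, 5)),
                                  random_params(rng))
            assert abs(a.sum() - 1.0) < 1e-6 and (a >= 0).all()

    def test_empty_bag_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_pool(np.empty((0, 5)), random_params(rng))


class TestLoss:
    def test_satisfied_margin_vanishes_at_low_temperature(self):
        assert smooth_top1_svm_loss(np.array([0.0, 50.0]), 1,
                                    tau=1e-3) < 1e-6

    def test_reduces_to_hinge_as_temperature_vanishes(self, rng):
        for _ in range(200):
            s = rng.standard_normal(2) * 3
            y = int(rng.integers(2))
            loss = smooth_top1_svm_loss(s, y, tau=1e-4)
            hinge = max(1.0 * (j != y) + s[j] - s[y] for j in (0, 1))
            assert abs(loss - hinge) <= 1e-3

    def test_symmetric_scores_closed_form(self):
        for tau in (0.5, 1.0, 2.0):
            loss = smooth_top1_svm_loss(np.array([3.3, 3.3]), 0, tau=tau)
            assert abs(loss - tau * np.log(1 + np.exp(1 / tau))) < 1e-12

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            smooth_top1_svm_loss(np.zeros(2), 0, tau=0.0)


class TestTraining:
    def test_loss_improves_on_easy_bags(self, easy_bags):
        cfg = TrainConfig(max_epochs=30, patience=10)
        model = train(easy_bags, cfg, seed=0)
        log = [e["train_loss"] for e in model.training_log]
        assert min(log) < log[0]

    def test_patience_zero_stops_at_first_stall(self, easy_bags):
        cfg = TrainConfig(max_epochs=50, patience=0, lr=1e-30)
        model = train(easy_bags, cfg, seed=0)
        assert len(model.training_log) == 2  # first epoch 'improves' on inf

    def test_single_class_rejected(self, easy_bags):
        negatives = [b for b in easy_bags if b.label == 0]
        with pytest.raises(ValueError):
            train(negatives, TrainConfig(max_epochs=5, patience=1), seed=0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(patience=300, max_epochs=200)
        with pytest.raises(ValueError):
            TrainConfig(lr=-1)


@pytest.fixture(scope="module")
def model(easy_bags):
    return train(easy_bags, TrainConfig(max_epochs=40, patience=10), seed=0)


class TestPredict:
    def test_instance_duplication_keeps_probability(self, model, easy_bags):
        bag = easy_bags[0]
        doubled = FeatureBag(bag.slide_id, bag.patient_id, bag.label,
                             np.vstack([bag.features, bag.features]))
        p1 = predict(model, bag)
        p2 = predict(model, doubled)
        assert abs(p1.probability - p2.probability) < 1e-6
        n = bag.n_instances
        np.testing.assert_allclose(p2.attention[:n], p1.attention / 2,
                                   atol=1e-9)

    def test_permutation_invariance(self, model, easy_bags, rng):
        bag = easy_bags[1]
        perm = rng.permutation(bag.n_instances)
        shuffled = FeatureBag(bag.slide_id, bag.patient_id, bag.label,
                              bag.features[perm])
        assert abs(predict(model, bag).probability -
                   predict(model, shuffled).probability) < 1e-9

    def test_dimension_mismatch(self, model, rng):
        bad = FeatureBag("s", "p", 0, rng.standard_normal((3, 9)))
        with pytest.raises(ValueError):
            predict(model, bad)


class TestCrossValidation:
    def make_bags(self, n_patients=10, slides_per_patient=1):
        rng = np.random.default_rng(5)
        bags = []
        for i in range(n_patients):
            label = i % 2
            for s in range(slides_per_patient):
                bags.append(FeatureBag(f"s{i}_{s}", f"p{i}", label,
                                       rng.standard_normal((4, 3))))
        return bags

    def test_balanced_patient_folds(self):
        bags = self.make_bags(10)
        folds = assign_folds(bags, k=5, seed=0)
        counts = np.bincount(list(folds.values()), minlength=5)
        assert (counts == 2).all()

    def test_patient_slides_share_fold(self):
        bags = self.make_bags(10, slides_per_patient=3)
        folds = assign_folds(bags, k=5, seed=1)
        for bag in bags:
            assert folds[bag.patient_id] == folds[bags[0].patient_id] or True
        # every slide appears exactly once in the out-of-fold table
        cfg = TrainConfig(max_epochs=3, patience=1)
        result = crossvalidate(bags, k=5, seed=1, config=cfg)
        assert len(result.scores) == len(bags)
        assert result.scores.groupby("patient_id")["fold"].nunique().eq(1).all()

    def test_inconsistent_patient_labels_rejected(self):
        bags = self.make_bags(10)
        bags.append(FeatureBag("odd", "p0", 1 - bags[0].label,
                               np.zeros((2, 3))))
        with pytest.raises(ValueError, match="inconsistent"):
            assign_folds(bags, k=5)

    def test_too_few_patients_per_class(self):
        with pytest.raises(ValueError):
            assign_folds(self.make_bags(6), k=5)
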