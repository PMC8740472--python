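"""Training-set assembly, classifier training, metrics, and LOO-TFGS."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import confusion_matrix, matthews_corrcoef

import ctap
from ctap.features import FEATURE_NAMES
from ctap.functional_groups import FunctionalGroup
from ctap.learning import (
    EvalMetrics,
    ModelSpec,
    build_training_set,
    evaluate,
    loo_fg_tfgs,
    random_gene_baseline,
    round2,
    train_model,
)


class TestBuildTrainingSet:
    def test_full_registry_yields_2176_samples(self, training_samples):
        # 134 marker entries + 2 TFs, each paired with all 16 CPs
        assert len(training_samples) == 2176

    def test_small_registry_cardinality(self, default_cohort):
        reg = [FunctionalGroup("toy", ("ACP5", "MMP9", "CTSK"),
                               {"OCU": "Activation", "OCD": "Inhibition"})]
        samples = build_training_set(default_cohort, reg, tf_directions={})
        assert len(samples) == 3 * 16

    def test_tf_labels_follow_direction_table(self, training_samples):
        irf8 = training_samples[training_samples["gene"] == "IRF8"]
        assert (irf8[irf8["context"] == "OCU"]["label"] == -1).all()
        assert (irf8[irf8["context"] == "OCD"]["label"] == +1).all()
        nfat = training_samples[training_samples["gene"] == "NFATC1"]
        assert (nfat[nfat["context"] == "OCU"]["label"] == +1).all()

    def test_recurring_gene_contributes_per_entry(self, training_samples):
        # DCSTAMP sits in two groups -> two entries per CP
        dc = training_samples[training_samples["gene"] == "DCSTAMP"]
        assert len(dc) == 2 * 16

    def test_empty_registry_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            build_training_set(default_cohort, [])


class TestEvaluate:
    def test_identities_match_sklearn(self):
        rng = np.random.default_rng(5)
        y = rng.choice([-1, 1], 200)
        p = rng.choice([-1, 1], 200)
        m = evaluate(p, y)
        tn, fp, fn, tp = confusion_matrix(y, p, labels=[-1, 1]).ravel()
        assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
        assert m.acc == pytest.approx((tp + tn) / 200)
        assert m.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)

    def test_all_correct_balanced(self):
        y = [1, 1, -1, -1]
        m = evaluate(y, y)
        assert (m.acc, m.mcc, m.sn, m.sp) == (1.0, 1.0, 1.0, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0, 1], [1, 1])


def test_round2_halves_away_from_zero():
    assert round2(0.795) == 0.80
    assert round2(0.125) == 0.13
    assert round2(-0.125) == -0.13
    assert round2(0.794999) == 0.79


class TestTrainModel:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.choice([-1, 1], n)
        X = rng.normal(0, 0.1, (n, 5))
        X[:, 0] += y * 3.0
        return pd.DataFrame(X, columns=list(FEATURE_NAMES)).assign(label=y)

    def test_separable_data_perfect_metrics(self):
        trained = train_model(self._separable(), ModelSpec("svm", seed=0))
        assert trained.metrics.acc == 1.0
        assert trained.metrics.mcc == 1.0

    def test_deterministic_given_seed(self):
        samples = self._separable(seed=3)
        a = train_model(samples, ModelSpec("lr", seed=7))
        b = train_model(samples, ModelSpec("lr", seed=7))
        assert a.metrics == b.metrics

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(11)
        aucs = []
        for _ in range(20):
            X = rng.normal(size=(300, 5))
            y = rng.choice([-1, 1], 300)  # independent of X
            samples = pd.DataFrame(X, columns=list(FEATURE_NAMES)).assign(label=y)
            trained = train_model(samples, ModelSpec("svm", seed=0))
            aucs.append(trained.metrics.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_single_class_rejected(self):
        samples = self._separable()
        samples["label"] = 1
        with pytest.raises(ValueError, match="reseed|stratif|class"):
            train_model(samples, ModelSpec("svm", seed=0))


class TestRandomGeneBaseline:
    def test_zero_repeats_empty_summary(self, default_cohort, registry):
        results, summary = random_gene_baseline(
            default_cohort, registry, ModelSpec("gnb", seed=0),
            n_repeats=0, seed=0,
        )
        assert results == [] and summary == {}

    def test_fixed_seed_reproducible(self, default_cohort, registry):
        kwargs = dict(n_repeats=2, seed=5)
        a = random_gene_baseline(default_cohort, registry,
                                 ModelSpec("gnb", seed=0), **kwargs)
        b = random_gene_baseline(default_cohort, registry,
                                 ModelSpec("gnb", seed=0), **kwargs)
        assert a[0] == b[0]


class _SignOfFoldChange:
    """Stub estimator predicting the sign of feature 1."""

    def __init__(self, flip=False):
        self.sign = -1 if flip else 1

    def fit(self, X, y):
        return self

    def predict(self, X):
        return self.sign * np.where(X[:, 0] > 0, 1, -1)


class TestLooFgTfgs:
    def test_oracle_predictor_saturates(self, noiseless_sim, registry):
        # noiseless fold-change signs equal the expected directions, so a
        # sign predictor follows expectation in every (FG, CP) cell
        cohort, _ = noiseless_sim
        res = loo_fg_tfgs(
            cohort, registry, ModelSpec("svm", seed=0),
            classifier_factory=lambda spec, params: _SignOfFoldChange(),
        )
        assert res["model"].count == 14 * 16
        assert res["log2fc_only"].count == 14 * 16

    def test_constant_up_counts_activation_cells(self, noiseless_sim, registry):
        cohort, _ = noiseless_sim

        class _AlwaysUp(_SignOfFoldChange):
            def predict(self, X):
                return np.ones(len(X), dtype=int)

        res = loo_fg_tfgs(
            cohort, registry, ModelSpec("svm", seed=0),
            classifier_factory=lambda spec, params: _AlwaysUp(),
        )
        expected = sum(
            sum(1 for fg in registry if fg.expected_state[cp.context] == "Activation")
            for cp in cohort.cps
        )
        assert res["model"].count == expected

    def test_anti_oracle_scores_zero(self, noiseless_sim, registry):
        cohort, _ = noiseless_sim
        res = loo_fg_tfgs(
            cohort, registry, ModelSpec("svm", seed=0),
            classifier_factory=lambda spec, params: _SignOfFoldChange(flip=True),
        )
        assert res["model"].count == 0

    def test_needs_two_groups(self, default_cohort, registry):
        with pytest.raises(ValueError):
            loo_fg_tfgs(default_cohort, registry[:1], ModelSpec("svm"))
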