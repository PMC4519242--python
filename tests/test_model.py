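"""Classifier machinery: metrics oracles, threshold rule, CV, importance."""

import numpy as np
import pandas as pd
import pytest

import pantherscape.model as pmodel
from pantherscape.cover import COVARIATES
from pantherscape.model import (
    ModelConfig,
    accuracy_metrics,
    auc_score,
    cross_validate,
    fit,
    select_threshold,
    variable_importance,
)
from conftest import random_labels_probs
from oracles import confusion_and_auc_oracle


class TestAccuracyMetrics:
    def test_hand_computed_confusion_example(self):
        # TP=40 FN=10 FP=5 TN=45
        labels = np.array([1] * 50 + [0] * 50)
        probs = np.array([0.9] * 40 + [0.1] * 10 + [0.9] * 5 + [0.1] * 45)
        rep = accuracy_metrics(labels, probs, 0.5)
        assert rep.pcc == pytest.approx(85.0)
        assert rep.sensitivity == pytest.approx(80.0)
        assert rep.specificity == pytest.approx(90.0)
        assert rep.kappa == pytest.approx(0.70)

    def test_perfect_probabilities(self):
        labels = np.array([1, 1, 0, 0])
        probs = np.array([1.0, 1.0, 0.0, 0.0])
        rep = accuracy_metrics(labels, probs, 0.5)
        assert rep.pcc == 100.0 and rep.kappa == 1.0 and rep.auc == 1.0

    def test_auc_pairwise_example(self):
        labels = np.array([1, 1, 0, 0])
        probs = np.array([0.9, 0.3, 0.5, 0.1])
        assert auc_score(labels, probs) == pytest.approx(0.75)

    def test_matches_brute_force_oracles_on_random_instances(self):
        """PCC/sens/spec/kappa/AUC equal independent oracles, 100 instances."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            labels, probs = random_labels_probs(rng, n)
            if rng.random() < 0.3:  # exercise midrank tie handling
                probs = np.round(probs, 1)
            t = float(rng.choice(probs))
            rep = accuracy_metrics(labels, probs, t)
            pcc, sens, spec, kappa, auc = confusion_and_auc_oracle(labels, probs, t)
            assert rep.pcc == pytest.approx(pcc)
            assert rep.sensitivity == pytest.approx(sens)
            assert rep.specificity == pytest.approx(spec)
            assert rep.kappa == pytest.approx(kappa)
            assert rep.auc == pytest.approx(auc)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        labels, probs = random_labels_probs(rng, 200)
        a1 = auc_score(labels, probs)
        a2 = auc_score(labels, 1 / (1 + np.exp(-7 * (probs - 0.3))))
        assert a1 == pytest.approx(a2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            accuracy_metrics(np.array([]), np.array([]), 0.5)
        with pytest.raises(ValueError):
            accuracy_metrics(np.array([1, 1]), np.array([0.6, 0.7]), 0.5)


class TestSelectThreshold:
    def test_enumeration_example(self):
        labels = np.array([1, 1, 0, 0])
        probs = np.array([0.9, 0.8, 0.4, 0.2])
        res = select_threshold(labels, probs)
        assert res.threshold == pytest.approx(0.8)
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_symmetric_interleaved_scores_equalize(self):
        labels = np.array([0, 1, 0, 1, 0, 1])
        probs = np.array([0.1, 0.2, 0.4, 0.6, 0.8, 0.9])
        res = select_threshold(labels, probs)
        assert abs(res.sensitivity - res.specificity) <= 100 / 3 + 1e-9

    def test_gap_bound_on_random_instances(self):
        """|sens - spec| at the cutoff <= 100/min(n1, n0) points."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 80))
            labels, probs = random_labels_probs(rng, n)
            res = select_threshold(labels, probs)
            n1, n0 = labels.sum(), n - labels.sum()
            assert abs(res.sensitivity - res.specificity) <= 100 / min(n1, n0) + 1e-9

    def test_present_fraction_tracks_prevalence(self, small_model):
        """On well-separated data the cutoff classifies about a prevalence-
        sized fraction of cells as present."""
        fitted, table = small_model
        res = select_threshold(fitted.labels.to_numpy(), fitted.oob_P.to_numpy())
        frac = (fitted.oob_P >= res.threshold).mean()
        assert frac == pytest.approx(fitted.labels.mean(), abs=0.05)


class TestFit:
    def make_table(self, n, rng, signal=True):
        X = rng.normal(size=(n, len(COVARIATES)))
        eta = 2.5 * X[:, 0] - 2.0 * X[:, 3] if signal else np.zeros(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        df = pd.DataFrame(X, columns=list(COVARIATES))
        df["presence"] = y
        return df

    def test_separable_data_memorized(self):
        rng = np.random.default_rng(0)
        df = self.make_table(300, rng)
        df["presence"] = (df[COVARIATES[0]] > 0).astype(int)
        m = fit(df, ModelConfig(n_trees=100, seed=0))
        rep = accuracy_metrics(m.labels, m.resub_P, 0.5)
        assert rep.pcc >= 99.0

    def test_permuted_labels_null_auc_and_kappa(self):
        """Label permutation: OOB AUC near 0.5 and kappa near 0 at n=2000."""
        rng = np.random.default_rng(1)
        df = self.make_table(2000, rng)
        df["presence"] = rng.permutation(df["presence"].to_numpy())
        m = fit(df, ModelConfig(n_trees=200, seed=1))
        auc = auc_score(m.labels.to_numpy(), m.oob_P.to_numpy())
        assert 0.45 <= auc <= 0.55
        thr = select_threshold(m.labels.to_numpy(), m.oob_P.to_numpy())
        rep = accuracy_metrics(m.labels, m.oob_P, thr.threshold)
        assert abs(rep.kappa) <= 0.05

    def test_same_seed_identical_oob(self):
        rng = np.random.default_rng(2)
        df = self.make_table(300, rng)
        m1 = fit(df, ModelConfig(n_trees=50, seed=5))
        m2 = fit(df, ModelConfig(n_trees=50, seed=5))
        assert np.array_equal(m1.oob_P.to_numpy(), m2.oob_P.to_numpy())

    def test_single_class_rejected(self):
        rng = np.random.default_rng(3)
        df = self.make_table(50, rng)
        df["presence"] = 1
        with pytest.raises(ValueError, match="degenerate response"):
            fit(df, ModelConfig(n_trees=10, seed=0))

    def test_missing_values_error_lists_cells(self):
        rng = np.random.default_rng(4)
        df = self.make_table(50, rng)
        df.iloc[3, 0] = np.nan
        with pytest.raises(ValueError, match="missing covariate"):
            fit(df, ModelConfig(n_trees=10, seed=0))

    def test_oob_masks_reproduce_sklearn_oob_probabilities(self):
        """Our re-derived per-tree bootstrap masks rebuild the ensemble's own
        OOB vote probabilities exactly."""
        rng = np.random.default_rng(5)
        df = self.make_table(250, rng)
        m = fit(df, ModelConfig(n_trees=60, seed=3))
        X = df[list(COVARIATES)].to_numpy()
        masks = pmodel._oob_masks(m.forest, len(df))
        votes = np.zeros((len(df), 2))
        for t, tree in enumerate(m.forest.estimators_):
            proba = tree.predict_proba(X[masks[t]])
            votes[masks[t]] += proba
        counts = masks.sum(axis=0)
        ours = np.full(len(df), np.nan)
        have = counts > 0
        ours[have] = votes[have, 1] / votes[have].sum(axis=1)
        ref = m.forest.oob_decision_function_[:, 1]
        assert np.allclose(ours[have], ref[have], atol=1e-12)


class TestCrossValidate:
    def test_leave_one_out_partition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, len(COVARIATES)))
        df = pd.DataFrame(X, columns=list(COVARIATES))
        df["presence"] = [0, 1] * 10
        res = cross_validate(df, ModelConfig(n_trees=25, seed=0), k=20)
        assert len(res["held_out_P"]) == 20
        assert sorted(res["folds"].unique()) == list(range(20))
        assert res["folds"].value_counts().max() == 1

    def test_cv_close_to_oob_with_strong_signal(self, small_world, small_model):
        fitted, table = small_model
        thr = select_threshold(fitted.labels.to_numpy(), fitted.oob_P.to_numpy())
        oob = accuracy_metrics(fitted.labels, fitted.oob_P, thr.threshold)
        res = cross_validate(small_world["table"], ModelConfig(seed=7), k=10)
        assert res["pooled"].pcc == pytest.approx(oob.pcc, abs=3.0)

    def test_pure_noise_cv_pcc_near_majority_rate(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(600, len(COVARIATES)))
        df = pd.DataFrame(X, columns=list(COVARIATES))
        df["presence"] = (rng.random(600) < 0.3).astype(int)
        res = cross_validate(df, ModelConfig(n_trees=150, seed=8), k=10)
        majority = 100 * max(df["presence"].mean(), 1 - df["presence"].mean())
        # equal-sens/spec thresholding trades majority-class accuracy away,
        # so CV PCC sits at or below the majority rate but above chance
        assert 45.0 <= res["pooled"].pcc <= majority + 5.0


class TestVariableImportance:
    def test_constant_covariate_scores_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, len(COVARIATES)))
        df = pd.DataFrame(X, columns=list(COVARIATES))
        df[COVARIATES[4]] = 1.0
        df["presence"] = (X[:, 0] + rng.normal(0, 0.5, 300) > 0).astype(int)
        m = fit(df, ModelConfig(n_trees=100, seed=0))
        imp = variable_importance(m, df, n_permutations=5)
        assert imp.loc[COVARIATES[4], "accuracy_importance"] == pytest.approx(0.0, abs=1e-9)
        assert imp.loc[COVARIATES[4], "gini_importance"] == pytest.approx(0.0, abs=1e-9)
        assert imp.loc[COVARIATES[0], "rank"] == 1

    def test_standardized_scores_top_is_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, len(COVARIATES)))
        df = pd.DataFrame(X, columns=list(COVARIATES))
        df["presence"] = (X[:, 2] > 0).astype(int)
        m = fit(df, ModelConfig(n_trees=100, seed=1))
        imp = variable_importance(m, df, n_permutations=5)
        assert imp["accuracy_std"].max() == pytest.approx(1.0)
        assert imp["gini_std"].max() == pytest.approx(1.0)
        assert sorted(imp["rank"]) == list(range(1, len(COVARIATES) + 1))

    def test_duplicated_top_covariate_dilutes_importance(self):
        """A duplicate of the strongest predictor absorbs splits, lowering
        the original's permutation importance (shared-signal behaviour)."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, len(COVARIATES)))
        df = pd.DataFrame(X, columns=list(COVARIATES))
        df["presence"] = (X[:, 0] + rng.normal(0, 0.3, 400) > 0).astype(int)
        m_solo = fit(df, ModelConfig(n_trees=150, seed=2))
        imp_solo = variable_importance(m_solo, df, n_permutations=5)
        dup = df.copy()
        dup[COVARIATES[1]] = dup[COVARIATES[0]]  # clone the signal column
        m_dup = fit(dup, ModelConfig(n_trees=150, seed=2))
        imp_dup = variable_importance(m_dup, dup, n_permutations=5)
        assert (
            imp_dup.loc[COVARIATES[0], "accuracy_importance"]
            < imp_solo.loc[COVARIATES[0], "accuracy_importance"]
        )
        # Gini credit is shared between the two identical columns
        assert imp_dup.loc[COVARIATES[1], "gini_importance"] > 0.1 * imp_dup.loc[
            COVARIATES[0], "gini_importance"
        ]
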