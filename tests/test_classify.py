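"""Obesity-status classification, AUC metrics, bootstrap stability."""

import numpy as np
import pandas as pd
import pytest

import brainage_delta as bd
from brainage_delta.classify import ClassifierGrid

SMALL_GRID = ClassifierGrid(
    tolerance_values=(0.01,), c_values=np.logspace(-2, 2, 5)
)


def _labelled_problem(n, p, effect, seed):
    """Features with a group mean shift on the first column; col 0 is 'age'."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 1] += effect * y
    frame = pd.DataFrame(
        X, columns=["age"] + [f"f{j}" for j in range(1, p)]
    )
    return frame, y


class TestCvClassify:
    def test_separable_groups_high_auc(self):
        X, y = _labelled_problem(120, 6, effect=3.0, seed=1)
        res = bd.cv_classify(X, y, SMALL_GRID, k=5, repeats=3, seed=1)
        assert res.mean_auc > 0.95

    def test_determinism(self):
        X, y = _labelled_problem(80, 5, effect=1.0, seed=2)
        a = bd.cv_classify(X, y, SMALL_GRID, k=5, repeats=2, seed=3)
        b = bd.cv_classify(X, y, SMALL_GRID, k=5, repeats=2, seed=3)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)
        np.testing.assert_array_equal(a.oof_scores, b.oof_scores)

    def test_single_class_rejected(self):
        X, _ = _labelled_problem(40, 4, effect=0.0, seed=4)
        with pytest.raises(ValueError, match="classes"):
            bd.cv_classify(X, np.zeros(40, dtype=int), SMALL_GRID)

    def test_every_fold_contains_both_classes(self):
        from brainage_delta.classify import stratified_class_age_folds

        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 50)
        ages = rng.uniform(18, 89, 100)
        folds = stratified_class_age_folds(y, ages, k=10, seed=6)
        for f in range(10):
            assert len(np.unique(y[folds == f])) == 2


class TestAucSensSpec:
    def test_perfectly_ordered_scores(self):
        auc, _, _ = bd.auc_sens_spec(
            np.linspace(0, 1, 10), np.repeat([0, 1], 5)
        )
        assert auc == 1.0

    def test_separated_block_scores(self):
        auc, se, sp = bd.auc_sens_spec(
            np.array([0.9, 0.8, 0.3, 0.2]), np.array([1, 1, 0, 0])
        )
        assert (auc, se, sp) == (1.0, 1.0, 1.0)

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.uniform(0, 1, 60), 1)  # induce ties
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        auc, _, _ = bd.auc_sens_spec(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos
            for n in neg
        )
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_one_class_absent(self):
        with pytest.raises(ValueError):
            bd.auc_sens_spec(np.array([0.1, 0.9]), np.array([1, 1]))


class TestBootstrapStability:
    def test_null_feature_ci_spans_zero_in_most_replicates(self):
        covered = 0
        for rep in range(10):
            X, y = _labelled_problem(100, 5, effect=2.0, seed=20 + rep)
            stab = bd.bootstrap_stability(
                X, y, tolerance=0.01, C=1.0, n_boot=150, seed=rep
            )
            # column f2 carries no group signal
            j = stab.feature_names.index("f2")
            if stab.ci_low[j] <= 0.0 <= stab.ci_high[j]:
                covered += 1
        assert covered >= 9

    def test_dominant_signal_feature_flagged(self):
        X, y = _labelled_problem(150, 6, effect=3.0, seed=8)
        stab = bd.bootstrap_stability(
            X, y, tolerance=0.01, C=1.0, n_boot=200, seed=9
        )
        j = stab.feature_names.index("f1")
        assert abs(stab.z[j]) > 1.5
        assert not (stab.ci_low[j] <= 0.0 <= stab.ci_high[j])

    def test_determinism(self):
        X, y = _labelled_problem(80, 4, effect=1.0, seed=10)
        a = bd.bootstrap_stability(X, y, 0.01, 1.0, n_boot=120, seed=11)
        b = bd.bootstrap_stability(X, y, 0.01, 1.0, n_boot=120, seed=11)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)

    def test_minimum_bootstrap_count(self):
        X, y = _labelled_problem(40, 4, effect=1.0, seed=12)
        with pytest.raises(ValueError):
            bd.bootstrap_stability(X, y, 0.01, 1.0, n_boot=50)


class TestRankWeights:
    def _stability(self, coefs):
        coefs = np.asarray(coefs, dtype=float)
        spread = coefs.std()
        z = np.zeros_like(coefs) if spread == 0 else (coefs - coefs.mean()) / spread
        return bd.StabilityResult(
            feature_names=[f"roi{j}" for j in range(len(coefs))],
            mean_coef=coefs,
            ci_low=coefs - 0.1,
            ci_high=coefs + 0.1,
            z=z,
            influential=np.abs(z) > 1.5,
        )

    def test_all_equal_coefficients_nothing_influential(self):
        ranked = bd.rank_weights(self._stability(np.ones(10)))
        assert (ranked["z"] == 0).all()
        assert not ranked["influential"].any()

    def test_single_outlier_ranked_first(self):
        coefs = np.zeros(48)
        coefs[7] = 5.0
        ranked = bd.rank_weights(self._stability(coefs))
        assert ranked.iloc[0]["feature"] == "roi7"
        assert ranked.iloc[0]["influential"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(13)
        coefs = rng.normal(size=20)
        ranked = bd.rank_weights(self._stability(coefs))
        oracle = np.argsort(-coefs)
        assert ranked["feature"].tolist() == [f"roi{j}" for j in oracle]

    def test_sign_interpretation_convention(self):
        ranked = bd.rank_weights(self._stability([-1.0, 1.0]))
        by_feature = ranked.set_index("feature")["interpretation"]
        assert "normal-weight" in by_feature["roi0"]
        assert "obese" in by_feature["roi1"]


class TestRegionalSignalRecovery:
    def test_planted_roi_effects_recovered_with_correct_signs(self):
        """Group effects planted in designated ROIs (negative:
        sensorimotor-like volume loss; positive: occipital-like volume gain)
        are recovered in the |z|>1.5 influential set with the right signs in
        most replicates."""
        hits = 0
        n_rep = 5
        for rep in range(n_rep):
            effect = bd.EffectSpec(
                accel_years=0.0,
                noise_sd=0.1,
                obese_roi_offsets={0: -0.15, 1: -0.15, 47: 0.15},
            )
            cohort = bd.generate_cohort(260, 0.5, seed=100 + rep)
            gm = bd.generate_gm_features(cohort, effect=effect, seed=200 + rep)
            table = cohort.table.set_index("id")
            X = gm.drop(columns=["id"]).copy()
            X.insert(0, "age", table.loc[gm["id"], "age"].to_numpy())
            X.insert(
                1, "sex",
                (table.loc[gm["id"], "sex"] == "male").astype(int).to_numpy(),
            )
            y = (table.loc[gm["id"], "bmi_class"] == "obese").astype(int)
            stab = bd.bootstrap_stability(
                X, y.to_numpy(), tolerance=0.01, C=1.0, n_boot=150,
                seed=300 + rep,
            )
            frame = stab.to_frame().set_index("feature")
            ok = (
                frame.loc["gm_roi_00", "influential"]
                and frame.loc["gm_roi_00", "mean_coef"] < 0
                and frame.loc["gm_roi_01", "influential"]
                and frame.loc["gm_roi_01", "mean_coef"] < 0
                and frame.loc["gm_roi_47", "influential"]
                and frame.loc["gm_roi_47", "mean_coef"] > 0
            )
            hits += bool(ok)
        assert hits >= 4  # >= 80% of replicates
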