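"""Pre-selection, SMOTE, stepwise partial-F selection, regression classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stratcorr import (
    Dataset,
    GroupPair,
    PreselectionConfig,
    StepwiseConfig,
    predict,
    preselect_features,
    smote_balance,
    stepwise_select,
    train_classifier,
)


def two_group_dataset(a_values, b_values, name="f"):
    a_values, b_values = np.asarray(a_values, float), np.asarray(b_values, float)
    n = len(a_values) + len(b_values)
    return Dataset(
        [f"s{i}" for i in range(n)],
        ["A"] * len(a_values) + ["B"] * len(b_values),
        pd.DataFrame({name: np.concatenate([a_values, b_values])}),
        pd.DataFrame({"age": np.zeros(n) + np.arange(n)}),
    )


PAIR = GroupPair("A", "B")


class TestPreselection:
    def test_too_much_missingness_excludes_feature(self):
        vals = np.concatenate([np.zeros(10), np.ones(10)])  # perfectly separated
        ds = two_group_dataset(vals[:10], vals[10:])
        ds.features.iloc[:3, 0] = np.nan  # 15% missing
        cfg = PreselectionConfig(max_missing_fraction=0.10, p_threshold=0.05)
        assert preselect_features(ds, PAIR, cfg) == []

    def test_identical_group_means_excluded(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        ds = two_group_dataset(base, base)  # exactly equal distributions
        cfg = PreselectionConfig(p_threshold=0.01)
        assert preselect_features(ds, PAIR, cfg) == []

    def test_pooled_t_on_printed_toy_values(self):
        # groups (1,2,3,4) vs (6,7,8,9): pooled t = -5 / sqrt(5/3 * 1/2)
        ds = two_group_dataset([1, 2, 3, 4], [6, 7, 8, 9])
        t_hand = -5.0 / np.sqrt((5.0 / 3.0) * 0.5)
        res = stats.ttest_ind([1, 2, 3, 4], [6, 7, 8, 9], equal_var=True)
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.pvalue == pytest.approx(0.00153, abs=5e-5)
        cfg = PreselectionConfig(p_threshold=0.01)
        assert preselect_features(ds, PAIR, cfg) == ["f"]

    def test_welch_variant_differs_under_unequal_variance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, 30)
        b = rng.normal(0.2, 3.0, 8)
        ds = two_group_dataset(a, b)
        pooled = stats.ttest_ind(a, b, equal_var=True).pvalue
        welch = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert pooled != pytest.approx(welch)
        keep_pooled = preselect_features(ds, PAIR, PreselectionConfig(p_threshold=0.5))
        keep_welch = preselect_features(
            ds, PAIR, PreselectionConfig(p_threshold=0.5, welch=True)
        )
        assert (keep_pooled == ["f"]) == (pooled <= 0.5)
        assert (keep_welch == ["f"]) == (welch <= 0.5)

    def test_all_features_untestable_errors(self):
        ds = two_group_dataset([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        ds.features.iloc[3:, 0] = np.nan  # group B has no values
        with pytest.raises(ValueError, match="non-missing"):
            preselect_features(ds, PAIR, PreselectionConfig(max_missing_fraction=1.0))


class TestSmote:
    def test_balanced_input_unchanged(self):
        ds = two_group_dataset(np.arange(5.0), np.arange(5.0) + 10)
        out = smote_balance(ds, PAIR, rng=0)
        assert out == ds

    def test_counts_equal_after_balancing(self):
        rng = np.random.default_rng(2)
        ds = two_group_dataset(rng.normal(size=4), rng.normal(size=13))
        out = smote_balance(ds, PAIR, rng=2)
        counts = out.groups.value_counts()
        assert counts["A"] == counts["B"] == 13

    def test_synthetics_lie_in_minority_segment_hull(self):
        # minority = two 1-D points at 0 and 1: every synthetic must fall in [0,1]
        ds = two_group_dataset([0.0, 1.0], np.linspace(5, 6, 5))
        out = smote_balance(ds, PAIR, k_neighbors=1, rng=7)
        synth = out.features["f"][out.groups.to_numpy() == "A"].to_numpy()[2:]
        assert len(synth) == 3
        assert ((synth >= 0.0) & (synth <= 1.0)).all()

    def test_originals_preserved(self):
        rng = np.random.default_rng(3)
        ds = two_group_dataset(rng.normal(size=3), rng.normal(size=9))
        out = smote_balance(ds, PAIR, rng=3)
        pd.testing.assert_frame_equal(
            out.features.iloc[: ds.n_subjects].reset_index(drop=True),
            ds.features.reset_index(drop=True),
        )

    def test_minority_of_one_errors(self):
        ds = two_group_dataset([0.0], np.arange(5.0))
        with pytest.raises(ValueError, match="< 2"):
            smote_balance(ds, PAIR, rng=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        ds = two_group_dataset(rng.normal(size=4), rng.normal(size=11))
        a = smote_balance(ds, PAIR, rng=123)
        b = smote_balance(ds, PAIR, rng=123)
        assert a == b


def audit_stepwise_fixed_point(x: pd.DataFrame, y, selected, config):
    """Exhaustive partial-F audit of a stepwise solution.

    No excluded feature may be addable at p < p_enter and no included
    feature removable at p > p_remove.
    """
    def rss(cols):
        design = np.column_stack([x[list(cols)].to_numpy(), np.ones(len(y))])
        coef, *_ = np.linalg.lstsq(design, np.asarray(y, float), rcond=None)
        r = np.asarray(y, float) - design @ coef
        return float(r @ r)

    n = len(y)
    sel = list(selected)
    rss_sel = rss(sel)
    p_full = len(sel) + 1
    for name in x.columns:
        if name in sel or x[name].std() == 0:
            continue
        df = n - (p_full + 1)
        f = max(rss_sel - rss(sel + [name]), 0) / (max(rss(sel + [name]), 1e-12) / df)
        assert stats.f.sf(f, 1, df) >= config.p_enter, f"addable feature {name} left out"
    for name in sel:
        rest = [c for c in sel if c != name]
        df = n - p_full
        f = max(rss(rest) - rss_sel, 0) / (max(rss_sel, 1e-12) / df)
        assert stats.f.sf(f, 1, df) <= config.p_remove, f"removable feature {name} kept"


class TestStepwise:
    def test_zero_candidates_empty_selection(self):
        assert stepwise_select(pd.DataFrame(index=range(10)), np.zeros(10)) == []

    def test_selects_only_informative_feature(self):
        rng = np.random.default_rng(10)
        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1 + rng.normal(0, 0.1, n)
        x = pd.DataFrame({"x1": x1, "x2": x2})
        cfg = StepwiseConfig()
        selected = stepwise_select(x, y, cfg)
        assert selected == ["x1"]
        audit_stepwise_fixed_point(x, y, selected, cfg)

    def test_orthogonalized_feature_not_selected(self):
        # residualize x against y so their correlation is exactly 0
        rng = np.random.default_rng(11)
        y = rng.normal(size=50)
        raw = rng.normal(size=50)
        yc = y - y.mean()
        x = raw - ((raw - raw.mean()) @ yc / (yc @ yc)) * yc
        assert abs(np.corrcoef(x, y)[0, 1]) < 1e-10
        assert stepwise_select(pd.DataFrame({"x": x}), y, StepwiseConfig()) == []

    def test_constant_feature_skipped(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=40)
        x = pd.DataFrame({"const": np.ones(40), "x1": y + rng.normal(0, 0.1, 40)})
        assert stepwise_select(x, y) == ["x1"]

    def test_collinear_duplicate_not_double_selected(self):
        rng = np.random.default_rng(13)
        n = 100
        x1 = rng.normal(size=n)
        y = x1 + rng.normal(0, 0.2, n)
        x = pd.DataFrame({"x1": x1, "dup": 2.0 * x1})
        selected = stepwise_select(x, y)
        assert len(selected) == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_fixed_point_on_random_toys(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = 80
        k = int(rng.integers(2, 6))
        x = pd.DataFrame(
            rng.normal(size=(n, k)), columns=[f"x{j}" for j in range(k)]
        )
        beta = rng.choice([0.0, 0.0, 0.5, 1.0], size=k)
        y = x.to_numpy() @ beta + rng.normal(0, 1.0, n)
        cfg = StepwiseConfig()
        selected = stepwise_select(x, y, cfg)
        audit_stepwise_fixed_point(x, y, selected, cfg)


class TestClassifier:
    def separable(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        a = -1.0 + rng.normal(0, 0.01, n // 2)
        b = 1.0 + rng.normal(0, 0.01, n // 2)
        return two_group_dataset(a, b)

    def test_separable_groups_train_accuracy_one(self):
        ds = self.separable()
        clf = train_classifier(ds, PAIR, seed=1)
        preds = predict(clf, ds)
        assert (preds == ds.groups.to_numpy()).mean() == 1.0

    def test_same_seed_bit_identical_weights(self):
        rng = np.random.default_rng(20)
        ds = two_group_dataset(rng.normal(size=9), rng.normal(1.2, 1, 21))
        c1 = train_classifier(ds, PAIR, seed=99)
        c2 = train_classifier(ds, PAIR, seed=99)
        assert np.array_equal(c1.weights, c2.weights)
        assert c1.selected_features == c2.selected_features

    def test_chance_accuracy_on_label_independent_data(self):
        # labels carry no signal: held-out accuracy should sit at 0.5
        rng = np.random.default_rng(21)
        accs = []
        for _ in range(60):
            x = rng.normal(size=(200, 5))
            labels = np.array(["A", "B"])[rng.integers(0, 2, 200)]
            ds = Dataset(
                [f"s{i}" for i in range(200)],
                labels,
                pd.DataFrame(x, columns=[f"f{j}" for j in range(5)]),
                pd.DataFrame({"age": np.zeros(200)}),
            )
            train = ds.subset_subjects(np.arange(200) < 150)
            test = ds.subset_subjects(np.arange(200) >= 150)
            clf = train_classifier(train, PAIR, seed=int(rng.integers(2**31)))
            accs.append((predict(clf, test) == test.groups.to_numpy()).mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_tie_score_goes_to_class_coded_one(self):
        from stratcorr import FittedClassifier

        clf = FittedClassifier(
            ("f",), np.array([0.0, 0.5]), 0.5, {"A": 0, "B": 1}, {"f": 0.0}
        )
        ds = two_group_dataset([0.0], [0.0])
        assert list(predict(clf, ds)) == ["B", "B"]

    def test_intercept_only_fallback_predicts_constant(self):
        rng = np.random.default_rng(22)
        ds = two_group_dataset(rng.normal(size=15), rng.normal(size=15))
        clf = train_classifier(ds, PAIR, seed=5)
        assert clf.selected_features == ()
        preds = predict(clf, ds)
        assert len(set(preds)) == 1

    def test_missing_values_imputed_from_training_means(self):
        ds = self.separable()
        clf = train_classifier(ds, PAIR, seed=2)
        probe = two_group_dataset([np.nan], [np.nan])
        scores = clf.scores(probe.features)
        expect = clf.training_means["f"] * clf.weights[0] + clf.weights[1]
        np.testing.assert_allclose(scores, expect)
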