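"""Repeated shared-split cross-validation and method comparison.

The four nuisance-handling methods — ``original`` (no adjustment),
``correction`` (reference-group regression residualization),
``stratification`` (per-target-subject training-subset selection) and
``combination`` (stratify, then correct with the full-training-set model)
— are compared on an identical sequence of random 90/10 train/test splits,
so per-repeat accuracies are positionally paired and a paired t-test on
the per-repeat differences is valid at face value. (The well-known caveat
that repeated-CV accuracies are not independent applies; the paired test
is reported as-is.)

Subjects outside the study-group pair (e.g. healthy controls in a stable-
vs-progressive MCI run) are assigned to every training set: they are never
classified, but the correction model needs them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import (
    FittedClassifier,
    StepwiseConfig,
    predict,
    train_classifier,
)
from .core import Dataset, GroupPair
from .correction import correct_features, fit_and_correct, fit_nuisance_model
from .stratification import make_rule, stratify

__all__ = [
    "CVPlan",
    "MethodResult",
    "EvalConfig",
    "accuracy",
    "make_cv_plan",
    "run_method",
    "paired_compare",
    "search_nuisance_subsets",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("original", "correction", "stratification", "combination")


def accuracy(predicted: Sequence, truth: Sequence) -> float:
    """Fraction of subjects assigned their true group label (in [0, 1])."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted/truth must be equal-length and non-empty")
    return float(np.mean(predicted == truth))


@dataclass(frozen=True)
class CVPlan:
    """A fixed sequence of train/test splits shared across all methods.

    ``splits`` holds (train_ids, test_ids) tuples over subject ids. Test
    sets contain only pair-eligible subjects; training sets additionally
    contain every out-of-pair subject.
    """

    n_repeats: int
    test_fraction: float
    seed: int
    splits: tuple[tuple[tuple, tuple], ...]

    def __post_init__(self) -> None:
        if len(self.splits) != self.n_repeats:
            raise ValueError("splits length must equal n_repeats")


def make_cv_plan(
    dataset: Dataset,
    pair: GroupPair,
    n_repeats: int = 100,
    test_fraction: float = 0.10,
    seed: int = 0,
    group_stratified: bool = False,
) -> CVPlan:
    """Random repeated 90/10 splits of the pair-eligible subjects.

    Plain random sampling by default; ``group_stratified`` draws the test
    fraction within each study group separately. Deterministic given seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    eligible_mask = dataset.group_mask(*pair.labels)
    others = list(dataset.subject_ids[~eligible_mask])
    for g in pair.labels:
        if int(dataset.group_mask(g).sum()) < 10:
            raise ValueError(f"fewer than 10 subjects in study group {g!r}")
    rng = np.random.default_rng(seed)
    splits = []
    if group_stratified:
        per_group = [list(dataset.subject_ids[dataset.group_mask(g)]) for g in pair.labels]
    eligible = list(dataset.subject_ids[eligible_mask])
    for _ in range(n_repeats):
        if group_stratified:
            test: list = []
            for ids in per_group:
                k = max(1, round(test_fraction * len(ids)))
                perm = rng.permutation(len(ids))
                test += [ids[i] for i in perm[:k]]
        else:
            k = max(1, round(test_fraction * len(eligible)))
            perm = rng.permutation(len(eligible))
            test = [eligible[i] for i in perm[:k]]
        test_set = set(test)
        train = [i for i in eligible if i not in test_set] + others
        splits.append((tuple(train), tuple(test)))
    return CVPlan(n_repeats, test_fraction, seed, tuple(splits))


@dataclass(frozen=True)
class MethodResult:
    """Per-repeat accuracies for one (method, nuisance subset) combination."""

    method: str
    nuisance_subset: tuple[str, ...]
    feature_group: str
    per_repeat_accuracy: np.ndarray

    def __post_init__(self) -> None:
        acc = np.asarray(self.per_repeat_accuracy, dtype=float)
        object.__setattr__(self, "per_repeat_accuracy", acc)
        object.__setattr__(self, "nuisance_subset", tuple(self.nuisance_subset))
        if acc.ndim != 1 or acc.size == 0:
            raise ValueError("per_repeat_accuracy must be a non-empty vector")
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_repeat_accuracy.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.per_repeat_accuracy.std(ddof=1)) if len(self.per_repeat_accuracy) > 1 else 0.0


@dataclass(frozen=True)
class EvalConfig:
    """Knobs shared by every method run on one dataset/pair."""

    stepwise: StepwiseConfig = field(default_factory=StepwiseConfig)
    smote_k: int = 5
    alpha: float = 1.0
    min_group_size: int = 10
    fallback: Literal["either", "both"] = "either"
    feature_names: tuple[str, ...] | None = None  # None = all features
    feature_group: str = "features"
    seed: int = 0  # base seed for per-repeat classifier randomness


def _repeat_seed(base_seed: int, repeat: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([base_seed, repeat]))


def _features(dataset: Dataset, config: EvalConfig) -> list[str]:
    return list(config.feature_names) if config.feature_names is not None else dataset.feature_names


def run_method(
    dataset: Dataset,
    pair: GroupPair,
    method: str,
    nuisance_subset: Sequence[str],
    plan: CVPlan,
    config: EvalConfig = EvalConfig(),
) -> MethodResult:
    """Evaluate one method over the shared CV plan; returns per-repeat accuracies.

    Per repeat: ``original`` trains on the raw training split; ``correction``
    fits the nuisance model on the split's reference subjects and corrects
    train and test before training; ``stratification`` classifies each test
    subject with a classifier trained on that subject's stratified training
    subset; ``combination`` stratifies per subject and corrects the subset
    (and the subject) with the model fitted on the full training split.
    A failure inside any repeat propagates — repeats are never silently
    skipped.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    nuisance_subset = tuple(nuisance_subset)
    if method != "original" and method != "correction" and not nuisance_subset:
        raise ValueError(f"method {method!r} requires at least one nuisance feature")
    # empty-subset correction is a no-op: reduce to the original path so the
    # reduction identity holds bit-for-bit
    effective = "original" if (method == "correction" and not nuisance_subset) else method

    feats = _features(dataset, config)
    ref_label = pair.resolve_reference(dataset.groups) if effective in ("correction", "combination") else None
    rule = None
    if effective in ("stratification", "combination"):
        rule = make_rule(dataset, nuisance_subset, config.alpha, config.min_group_size, config.fallback)

    accs = np.empty(plan.n_repeats)
    for r, (train_ids, test_ids) in enumerate(plan.splits):
        rng = _repeat_seed(config.seed, r)
        train = dataset.subset_by_ids(train_ids)
        test = dataset.subset_by_ids(test_ids)
        truth = test.groups.to_numpy()

        if effective == "original":
            clf = train_classifier(train, pair, config.stepwise, config.smote_k, rng, feats)
            accs[r] = accuracy(predict(clf, test), truth)
        elif effective == "correction":
            _, ctrain, ctest = fit_and_correct(train, test, feats, nuisance_subset, ref_label)
            clf = train_classifier(ctrain, pair, config.stepwise, config.smote_k, rng, feats)
            accs[r] = accuracy(predict(clf, ctest), truth)
        else:
            model = None
            if effective == "combination":
                model = fit_nuisance_model(train, feats, nuisance_subset, ref_label)
            preds = np.empty(len(test_ids), dtype=object)
            cache: dict[frozenset, FittedClassifier] = {}
            # classifiers are deterministic given the subset and the repeat
            # seed, so caching by subset identity cannot change results
            for t in range(test.n_subjects):
                target = test.subset_subjects(np.arange(test.n_subjects) == t)
                subset = stratify(train, target.nuisance.iloc[0].to_dict(), rule, pair)
                key = frozenset(subset.subject_ids)
                if key not in cache:
                    sub = subset if model is None else correct_features(subset, model)
                    cache[key] = train_classifier(
                        sub, pair, config.stepwise, config.smote_k,
                        _repeat_seed(config.seed, r), feats,
                    )
                target_in = target if model is None else correct_features(target, model)
                preds[t] = predict(cache[key], target_in)[0]
            accs[r] = accuracy(preds, truth)
    return MethodResult(method, nuisance_subset, config.feature_group, accs)


@dataclass(frozen=True)
class PairedComparison:
    mean_difference: float
    t_statistic: float
    p_value: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.t_statistic) and np.isfinite(self.p_value)


def paired_compare(a: MethodResult, b: MethodResult) -> PairedComparison:
    """Two-sided paired t-test on per-repeat accuracy differences (a - b).

    Requires results computed on the same CV plan (equal lengths >= 2). A
    zero-variance difference vector leaves t and p undefined (NaN).
    """
    x, y = a.per_repeat_accuracy, b.per_repeat_accuracy
    if len(x) != len(y):
        raise ValueError("results have different repeat counts; plans must match")
    if len(x) < 2:
        raise ValueError("need at least 2 repeats")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedComparison(float(d.mean()), np.nan, np.nan)
    res = stats.ttest_rel(x, y)
    return PairedComparison(float(d.mean()), float(res.statistic), float(res.pvalue))


def search_nuisance_subsets(
    dataset: Dataset,
    pair: GroupPair,
    methods: Sequence[str],
    nuisance_names: Sequence[str],
    plan: CVPlan,
    config: EvalConfig = EvalConfig(),
    max_nuisances: int = 12,
) -> pd.DataFrame:
    """Evaluate every non-empty nuisance subset for every requested method.

    Mirrors the exhaustive search design: single nuisances first, then all
    pairs, and so on, all on the shared CV plan. Returns a tidy frame with
    one row per (method, subset) ranked by mean accuracy, plus the
    ``original`` baseline as an empty-subset row. Use
    :func:`best_by_subset_size` on the result for the accuracy-vs-size view.
    """
    nuisance_names = list(nuisance_names)
    if len(nuisance_names) > max_nuisances:
        raise ValueError(
            f"{len(nuisance_names)} nuisances would enumerate "
            f"{2 ** len(nuisance_names) - 1} subsets; raise max_nuisances to confirm"
        )
    rows = []

    def add(result: MethodResult) -> None:
        rows.append(
            {
                "method": result.method,
                "nuisance_subset": "+".join(result.nuisance_subset),
                "subset_size": len(result.nuisance_subset),
                "feature_group": result.feature_group,
                "mean_accuracy": result.mean_accuracy,
                "sd_accuracy": result.sd_accuracy,
                "per_repeat": result.per_repeat_accuracy,
            }
        )

    add(run_method(dataset, pair, "original", (), plan, config))
    subsets = [
        combo
        for size in range(1, len(nuisance_names) + 1)
        for combo in itertools.combinations(nuisance_names, size)
    ]
    for method in methods:
        if method == "original":
            continue
        for combo in subsets:
            add(run_method(dataset, pair, method, combo, plan, config))
    out = pd.DataFrame(rows).sort_values("mean_accuracy", ascending=False, kind="stable")
    return out.reset_index(drop=True)


def best_by_subset_size(results: pd.DataFrame, method: str) -> pd.DataFrame:
    """Best mean accuracy per nuisance-subset size for one method."""
    sub = results[results["method"] == method]
    idx = sub.groupby("subset_size")["mean_accuracy"].idxmax()
    return (
        sub.loc[idx, ["subset_size", "nuisance_subset", "mean_accuracy"]]
        .sort_values("subset_size")
        .reset_index(drop=True)
    )


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Best subset per method with the paired p-value against the baseline."""
    base = results[results["method"] == "original"].iloc[0]
    base_res = MethodResult("original", (), base["feature_group"], base["per_repeat"])
    rows = []
    for method in results["method"].unique():
        sub = results[results["method"] == method]
        best = sub.loc[sub["mean_accuracy"].idxmax()]
        row = {
            "method": method,
            "best_subset": best["nuisance_subset"],
            "mean_accuracy": best["mean_accuracy"],
            "sd_accuracy": best["sd_accuracy"],
        }
        if method != "original":
            cmp = paired_compare(
                MethodResult(method, (), best["feature_group"], best["per_repeat"]),
                base_res,
            )
            row["p_vs_original"] = cmp.p_value
        else:
            row["p_vs_original"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
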