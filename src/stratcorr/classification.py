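"""Classifier stack: pre-selection, SMOTE balancing, stepwise selection, OLS classifier.

The pipeline discriminates two study groups from the classification-feature
block of a :class:`~stratcorr.core.Dataset`:

1. feature pre-selection — drop features with too many missing values or a
   non-significant two-sample t-test between the groups;
2. mean imputation of residual missing values (training means only);
3. SMOTE oversampling of the minority study group to equal class sizes;
4. sequential stepwise feature selection by partial F-tests (forward entry
   at p < 0.05, backward removal at p > 0.10);
5. an ordinary least-squares regression of the 0/1 class indicator on the
   selected features, thresholded at 0.5.

The regression-on-indicator classifier is deliberately simple: with the
classes balanced by SMOTE, the 0.5 threshold equals the balanced prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Dataset, GroupPair

__all__ = [
    "PreselectionConfig",
    "StepwiseConfig",
    "FittedClassifier",
    "preselect_features",
    "smote_balance",
    "stepwise_select",
    "train_classifier",
    "predict",
]

logger = logging.getLogger(__name__)

_RSS_FLOOR = 1e-12  # guards partial-F denominators on perfectly separable toys


@dataclass(frozen=True)
class PreselectionConfig:
    """Feature pre-selection thresholds.

    ``max_missing_fraction``: drop features with more than this fraction of
    missing values. ``p_threshold``: drop features whose two-sample t-test
    p-value between the study groups exceeds it (0.00001 suits an easy pair
    like controls vs AD, 0.01 a hard pair like stable vs progressive MCI).
    ``welch``: use the unequal-variance t-test instead of pooled-variance.
    """

    max_missing_fraction: float = 0.10
    p_threshold: float = 0.01
    welch: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in (0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass(frozen=True)
class StepwiseConfig:
    """Stepwise-selection entry/removal p-value thresholds (partial F-tests)."""

    p_enter: float = 0.05
    p_remove: float = 0.10
    max_steps: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.p_enter < self.p_remove < 1:
            raise ValueError("need 0 < p_enter < p_remove < 1")


@dataclass(frozen=True)
class FittedClassifier:
    """OLS-on-indicator classifier with its imputation means.

    ``weights`` holds one coefficient per selected feature plus the
    intercept (last entry). A score >= ``decision_threshold`` predicts the
    class coded 1 (ties go to class 1).
    """

    selected_features: tuple[str, ...]
    weights: np.ndarray
    decision_threshold: float
    class_codes: Mapping[str, int]
    training_means: Mapping[str, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        object.__setattr__(self, "selected_features", tuple(self.selected_features))
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "class_codes", dict(self.class_codes))
        object.__setattr__(self, "training_means", dict(self.training_means))
        if w.size != len(self.selected_features) + 1:
            raise ValueError("weights length must be selected feature count + 1")
        if sorted(self.class_codes.values()) != [0, 1]:
            raise ValueError("class_codes must map the two labels to 0 and 1")

    @property
    def label_for_code(self) -> dict[int, str]:
        return {code: label for label, code in self.class_codes.items()}

    def scores(self, features: pd.DataFrame) -> np.ndarray:
        cols = list(self.selected_features)
        absent = [c for c in cols if c not in features.columns]
        if absent:
            raise ValueError(f"selected feature columns absent: {absent}")
        if not cols:
            return np.full(len(features), self.weights[-1])
        x = features[cols].to_numpy(dtype=float)
        for j, c in enumerate(cols):
            col = x[:, j]
            col[~np.isfinite(col)] = self.training_means[c]
        return x @ self.weights[:-1] + self.weights[-1]


def preselect_features(
    dataset: Dataset, pair: GroupPair, config: PreselectionConfig
) -> list[str]:
    """Features passing the missingness and group-difference t-test screens.

    Missing fractions and tests are computed over the pair's study-group
    subjects only. Data are assumed normally distributed; the test is
    two-sided and pooled-variance unless ``config.welch``.
    """
    sub = dataset.subset_subjects(dataset.group_mask(*pair.labels))
    if sub.n_subjects == 0:
        raise ValueError("no subjects belong to the study-group pair")
    is_a = sub.group_mask(pair.group_a)
    is_b = sub.group_mask(pair.group_b)
    kept: list[str] = []
    any_testable = False
    for name in sub.feature_names:
        col = sub.features[name].to_numpy(dtype=float)
        a = col[is_a & np.isfinite(col)]
        b = col[is_b & np.isfinite(col)]
        if len(a) < 2 or len(b) < 2:
            continue
        any_testable = True
        if np.mean(~np.isfinite(col)) > config.max_missing_fraction:
            continue
        res = stats.ttest_ind(a, b, equal_var=not config.welch)
        if np.isfinite(res.pvalue) and res.pvalue <= config.p_threshold:
            kept.append(name)
    if not any_testable:
        raise ValueError(
            "every feature has < 2 non-missing values in one of the study groups"
        )
    return kept


def smote_balance(
    train: Dataset,
    pair: GroupPair,
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = None,
) -> Dataset:
    """Equalize the two study-group sizes by SMOTE oversampling.

    Synthetic minority samples are convex combinations x + u * (x_nn - x)
    of a random minority subject and one of its k nearest minority
    neighbors (Euclidean distance on the mean-imputed classification
    features, u uniform on [0, 1]). Originals are preserved; subjects
    outside the pair pass through untouched. An already balanced input is
    returned unchanged.
    """
    rng = np.random.default_rng(rng)
    n_a = int(train.group_mask(pair.group_a).sum())
    n_b = int(train.group_mask(pair.group_b).sum())
    if n_a == n_b:
        return train
    minority = pair.group_a if n_a < n_b else pair.group_b
    n_min, n_maj = min(n_a, n_b), max(n_a, n_b)
    if n_min < 2:
        raise ValueError(f"minority group {minority!r} has < 2 subjects")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")

    pair_means = train.subset_subjects(train.group_mask(*pair.labels)).features.mean()
    minority_ds = train.subset_subjects(train.group_mask(minority))
    x = minority_ds.features.fillna(pair_means).fillna(0.0).to_numpy(dtype=float)
    s = minority_ds.nuisance.copy()
    s = s.fillna(s.mean()).fillna(0.0).to_numpy(dtype=float)

    k = min(k_neighbors, n_min - 1)
    # pairwise distances on the imputed feature block; n_min is small
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]

    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    nbr = nn_idx[base, pick]
    new_x = x[base] + u[:, None] * (x[nbr] - x[base])
    new_s = s[base] + u[:, None] * (s[nbr] - s[base])

    existing = set(map(str, train.subject_ids))
    new_ids = []
    i = 0
    while len(new_ids) < n_new:
        cand = f"smote_{minority}_{i:05d}"
        if cand not in existing:
            new_ids.append(cand)
        i += 1
    synth = Dataset(
        new_ids,
        [minority] * n_new,
        pd.DataFrame(new_x, columns=train.features.columns),
        pd.DataFrame(new_s, columns=train.nuisance.columns),
    )
    return Dataset(
        list(train.subject_ids) + new_ids,
        list(train.groups) + [minority] * n_new,
        pd.concat([train.features, synth.features], axis=0, ignore_index=True),
        pd.concat([train.nuisance, synth.nuisance], axis=0, ignore_index=True),
    )


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid)


def _partial_f_pvalue(rss_reduced: float, rss_full: float, n: int, p_full: int) -> float:
    """p-value of the F-test comparing nested OLS fits differing by one term."""
    df_resid = n - p_full
    if df_resid <= 0:
        return 1.0
    num = max(rss_reduced - rss_full, 0.0)
    den = max(rss_full, _RSS_FLOOR) / df_resid
    return float(stats.f.sf(num / den, 1, df_resid))


def stepwise_select(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    config: StepwiseConfig = StepwiseConfig(),
) -> list[str]:
    """Sequential forward-entry / backward-removal feature selection.

    Starting from the empty model (intercept only), each iteration adds the
    excluded feature with the smallest partial-F p-value if it is below
    ``p_enter``, then removes the included feature with the largest partial-F
    p-value if it is above ``p_remove`` (one removal per iteration), until a
    fixed point or ``max_steps``. Constant and collinear candidates are
    skipped (a collinear feature cannot reduce the residual sum of squares,
    so its partial-F p-value is ~1).
    """
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{j}" for j in range(x.shape[1])]
    y = np.asarray(labels, dtype=float).ravel()
    n = len(y)
    if x.shape[0] != n:
        raise ValueError("features/labels length mismatch")

    candidates = [j for j in range(x.shape[1]) if x[:, j].std() > 0]
    skipped = [names[j] for j in range(x.shape[1]) if j not in candidates]
    if skipped:
        logger.warning("stepwise: skipping constant feature(s) %s", skipped)

    selected: list[int] = []
    intercept = np.ones((n, 1))
    for _ in range(config.max_steps):
        changed = False
        cur = np.hstack([x[:, selected], intercept]) if selected else intercept
        rss_cur = _rss(cur, y)
        # forward entry
        best_j, best_p = None, np.inf
        for j in candidates:
            if j in selected:
                continue
            p = _partial_f_pvalue(
                rss_cur, _rss(np.hstack([cur, x[:, [j]]]), y), n, cur.shape[1] + 1
            )
            if p < best_p:
                best_j, best_p = j, p
        if best_j is not None and best_p < config.p_enter:
            selected.append(best_j)
            changed = True
            cur = np.hstack([x[:, selected], intercept])
            rss_cur = _rss(cur, y)
        # backward removal, largest p first, one per iteration
        if len(selected) > 0:
            worst_i, worst_p = None, -np.inf
            for pos in range(len(selected)):
                rest = selected[:pos] + selected[pos + 1 :]
                reduced = np.hstack([x[:, rest], intercept]) if rest else intercept
                p = _partial_f_pvalue(_rss(reduced, y), rss_cur, n, cur.shape[1])
                if p > worst_p:
                    worst_i, worst_p = pos, p
            if worst_p > config.p_remove:
                del selected[worst_i]
                changed = True
        if not changed:
            break
    return [names[j] for j in selected]


def train_classifier(
    train: Dataset,
    pair: GroupPair,
    stepwise: StepwiseConfig = StepwiseConfig(),
    smote_k: int = 5,
    seed: int | np.random.Generator = 0,
    candidate_features: Sequence[str] | None = None,
) -> FittedClassifier:
    """Impute -> SMOTE-balance -> stepwise-select -> OLS on the 0/1 indicator.

    Only the pair's study-group subjects train the classifier; reference or
    other groups present in ``train`` are ignored here (they serve the
    correction model, not the classifier). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    cols = list(candidate_features) if candidate_features is not None else train.feature_names
    pair_ds = train.subset_subjects(train.group_mask(*pair.labels))
    for g in pair.labels:
        if not pair_ds.group_mask(g).any():
            raise ValueError(f"study group {g!r} absent from training data")

    means = pair_ds.features[cols].mean()
    training_means = {c: (float(means[c]) if np.isfinite(means[c]) else 0.0) for c in cols}
    imputed = pair_ds.features.copy()
    imputed[cols] = imputed[cols].fillna(pd.Series(training_means))
    pair_ds = pair_ds.with_features(imputed)

    balanced = smote_balance(pair_ds, pair, k_neighbors=smote_k, rng=rng)
    y = (balanced.groups.to_numpy() == pair.group_b).astype(float)
    selected = stepwise_select(balanced.features[cols], y, stepwise)

    if selected:
        xb = balanced.features[list(selected)].to_numpy(dtype=float)
        design = np.column_stack([xb, np.ones(len(y))])
        weights, *_ = np.linalg.lstsq(design, y, rcond=None)
    else:
        # intercept-only fallback: score = mean of the balanced labels (0.5)
        logger.warning("stepwise selected no features; intercept-only classifier")
        weights = np.array([float(y.mean())])

    return FittedClassifier(
        selected_features=tuple(selected),
        weights=weights,
        decision_threshold=0.5,
        class_codes={pair.group_a: 0, pair.group_b: 1},
        training_means=training_means,
    )


def predict(classifier: FittedClassifier, subjects: Dataset) -> np.ndarray:
    """Predicted group labels; scores at the threshold go to the class coded 1."""
    scores = classifier.scores(subjects.features)
    labels = classifier.label_for_code
    return np.where(
        scores >= classifier.decision_threshold, labels[1], labels[0]
    ).astype(object)
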