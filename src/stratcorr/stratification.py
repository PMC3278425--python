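"""Per-target-subject stratification of the training set.

For a target subject n, keep only the training subjects m whose nuisance
values all lie within a threshold of the target's:

    |s_j(m) - s_j(n)| <= th_j   for every used nuisance j,

with th_j = alpha * std(s_j) computed over the whole dataset. The selected
subset is a nuisance-homogeneous sub-population in which group differences
are more pronounced; a classifier is then trained per target subject on it.

If stratification leaves too few subjects in a study group (< 10 by
default), the full training set is used instead — no stratification for
that target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .core import Dataset, GroupPair
from .correction import NuisanceModel, correct_features, fit_nuisance_model

__all__ = ["StratificationRule", "make_rule", "stratify", "stratify_then_correct"]


@dataclass(frozen=True)
class StratificationRule:
    """Thresholds th_j = alpha * std(s_j) plus the small-sample fallback bound.

    ``fallback="either"`` (default) reverts to the full training set when
    either study group drops below ``min_group_size`` after selection;
    ``"both"`` requires both groups to drop below it.
    """

    nuisance_names: tuple[str, ...]
    alpha: float
    thresholds: Mapping[str, float]
    min_group_size: int = 10
    fallback: Literal["either", "both"] = "either"

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuisance_names", tuple(self.nuisance_names))
        object.__setattr__(self, "thresholds", dict(self.thresholds))
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        for name in self.nuisance_names:
            th = self.thresholds.get(name)
            if th is None or not np.isfinite(th) or th <= 0:
                raise ValueError(f"threshold for {name!r} must be finite and > 0")

    def to_records(self) -> list[dict]:
        return [
            {
                "nuisance": n,
                "threshold": float(self.thresholds[n]),
                "alpha": self.alpha,
                "min_group_size": self.min_group_size,
            }
            for n in self.nuisance_names
        ]


def make_rule(
    dataset: Dataset,
    nuisance_names: Sequence[str],
    alpha: float = 1.0,
    min_group_size: int = 10,
    fallback: Literal["either", "both"] = "either",
) -> StratificationRule:
    """Derive thresholds from the WHOLE dataset's nuisance standard deviations.

    Sample standard deviation (n-1 denominator), missing values skipped.
    The whole-dataset std is a global scale parameter, so it is computed
    once over all subjects, not per CV training split.
    """
    nuisance_names = tuple(nuisance_names)
    if not nuisance_names:
        raise ValueError("at least one nuisance feature is required")
    thresholds = {}
    for name in nuisance_names:
        if name not in dataset.nuisance.columns:
            raise ValueError(f"nuisance column {name!r} absent from dataset")
        sd = float(dataset.nuisance[name].std(ddof=1, skipna=True))
        if not np.isfinite(sd) or np.isclose(sd, 0.0):
            raise ValueError(f"nuisance {name!r} has zero variance in the dataset")
        thresholds[name] = alpha * sd
    return StratificationRule(nuisance_names, alpha, thresholds, min_group_size, fallback)


def stratify(
    train: Dataset,
    target_nuisance: Mapping[str, float],
    rule: StratificationRule,
    pair: GroupPair,
) -> Dataset:
    """Training subjects within every threshold of the target subject.

    Boundary ties (|s - s_target| exactly equal to the threshold) are
    included. Training subjects with a missing value in a rule nuisance
    never satisfy the rule. Returns the full training set when the fallback
    condition on the study-group counts fires.
    """
    keep = np.ones(train.n_subjects, dtype=bool)
    for name in rule.nuisance_names:
        target = target_nuisance.get(name)
        if target is None or not np.isfinite(target):
            raise ValueError(f"target subject has no value for nuisance {name!r}")
        s = train.nuisance[name].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            keep &= np.abs(s - float(target)) <= rule.thresholds[name]

    n_a = int((keep & train.group_mask(pair.group_a)).sum())
    n_b = int((keep & train.group_mask(pair.group_b)).sum())
    small_a, small_b = n_a < rule.min_group_size, n_b < rule.min_group_size
    triggered = (small_a or small_b) if rule.fallback == "either" else (small_a and small_b)
    if triggered:
        return train
    return train.subset_subjects(keep)


def stratify_then_correct(
    train: Dataset,
    target_nuisance: Mapping[str, float],
    rule: StratificationRule,
    pair: GroupPair,
    feature_names: Sequence[str],
    nuisance_names: Sequence[str],
    reference_group: str,
) -> tuple[Dataset, NuisanceModel]:
    """Stratify around the target, then correct the subset.

    The regression model is fitted on the FULL training set's reference
    group — not the stratified subset, whose reference sample may be too
    small for stable slope estimates (and under the linearity assumption
    the same parameters apply to every stratum). Returns the corrected
    stratified subset and the model, with which the caller corrects the
    target subject's own features.
    """
    model = fit_nuisance_model(train, feature_names, nuisance_names, reference_group)
    subset = stratify(train, target_nuisance, rule, pair)
    return correct_features(subset, model), model
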