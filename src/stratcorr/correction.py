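"""Control-referenced linear regression correction of nuisance effects.

The normal (non-disease) dependence of each classification feature c_i on
the nuisance features s_1..s_k is modelled by ordinary least squares fitted
on the reference group only,

    c_i(n) = a_i1 * s_1(n) + ... + a_ik * s_k(n) + b_i + e(n),

and the fitted effect (including the intercept) is then subtracted from
every subject of every group:

    c_i_corrected(n) = c_i(n) - (a_i . s(n) + b_i).

Because the intercept is subtracted too, the corrected reference-group
values of every feature have exactly zero mean — the residual property of
OLS — which downstream code and tests rely on. The procedure is the
data-correction arm of ANCOVA-style covariate adjustment: the reference
group carries no disease-related variability, so its regression slope
estimates only the nuisance trend (an age-atrophy slope, a gender offset)
and subtracting it leaves the disease signal untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Dataset

__all__ = ["NuisanceModel", "fit_nuisance_model", "correct_features", "fit_and_correct"]


@dataclass(frozen=True)
class NuisanceModel:
    """Per-feature OLS coefficients against the nuisance features.

    ``slopes`` has shape (n_features, n_nuisances); ``intercepts`` one entry
    per feature; ``n_reference`` the per-feature count of complete-case
    reference subjects used in that feature's fit.
    """

    feature_names: tuple[str, ...]
    nuisance_names: tuple[str, ...]
    slopes: np.ndarray
    intercepts: np.ndarray
    reference_group: str
    n_reference: np.ndarray

    def __post_init__(self) -> None:
        slopes = np.atleast_2d(np.asarray(self.slopes, dtype=float))
        intercepts = np.asarray(self.intercepts, dtype=float).ravel()
        n_ref = np.asarray(self.n_reference, dtype=int).ravel()
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "nuisance_names", tuple(self.nuisance_names))
        object.__setattr__(self, "slopes", slopes)
        object.__setattr__(self, "intercepts", intercepts)
        object.__setattr__(self, "n_reference", n_ref)
        f, k = len(self.feature_names), len(self.nuisance_names)
        if slopes.shape != (f, k):
            raise ValueError(f"slopes shape {slopes.shape} != ({f}, {k})")
        if intercepts.shape != (f,) or n_ref.shape != (f,):
            raise ValueError("intercepts/n_reference must have one entry per feature")
        if np.any(n_ref < k + 2):
            raise ValueError(
                "too few reference subjects for the number of nuisance features"
            )

    def predict_nuisance_effect(self, nuisance: pd.DataFrame) -> np.ndarray:
        """Fitted effect a_i . s(n) + b_i, shape (n_subjects, n_features)."""
        s = nuisance[list(self.nuisance_names)].to_numpy(dtype=float)
        return s @ self.slopes.T + self.intercepts

    # flat audit-friendly serialization: one record per feature/nuisance pair
    def to_records(self) -> list[dict]:
        recs = []
        for i, feat in enumerate(self.feature_names):
            for j, nuis in enumerate(self.nuisance_names):
                recs.append(
                    {
                        "feature": feat,
                        "nuisance": nuis,
                        "slope": float(self.slopes[i, j]),
                        "intercept": float(self.intercepts[i]),
                        "reference_group": self.reference_group,
                        "n_reference": int(self.n_reference[i]),
                    }
                )
        return recs

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1))


def fit_nuisance_model(
    train: Dataset,
    feature_names: Sequence[str],
    nuisance_names: Sequence[str],
    reference_group: str,
) -> NuisanceModel:
    """Fit the reference-group OLS of each feature on the nuisance features.

    One joint multiple regression per classification feature (an intercept
    plus one coefficient per nuisance). Reference subjects with a missing
    value in the feature or any involved nuisance are dropped from that
    feature's fit (complete-case per feature).

    Raises
    ------
    ValueError
        If a nuisance has zero variance within the reference group, or too
        few complete-case reference subjects remain (< n_nuisances + 2).
    """
    feature_names = tuple(feature_names)
    nuisance_names = tuple(nuisance_names)
    if not nuisance_names:
        raise ValueError("at least one nuisance feature is required")
    ref = train.subset_subjects(train.group_mask(reference_group))
    if ref.n_subjects == 0:
        raise ValueError(f"no subjects with reference label {reference_group!r}")
    missing = [c for c in (*feature_names, *nuisance_names)
               if c not in ref.features.columns and c not in ref.nuisance.columns]
    if missing:
        raise ValueError(f"columns absent from dataset: {missing}")

    s_all = ref.nuisance[list(nuisance_names)].to_numpy(dtype=float)
    k = len(nuisance_names)
    slopes = np.empty((len(feature_names), k))
    intercepts = np.empty(len(feature_names))
    n_used = np.empty(len(feature_names), dtype=int)

    for i, feat in enumerate(feature_names):
        c = ref.features[feat].to_numpy(dtype=float)
        ok = np.isfinite(c) & np.all(np.isfinite(s_all), axis=1)
        n = int(ok.sum())
        if n < k + 2:
            raise ValueError(
                f"feature {feat!r}: only {n} complete-case reference subjects "
                f"(need >= {k + 2})"
            )
        s = s_all[ok]
        if np.any(np.isclose(s.std(axis=0), 0.0)):
            flat = [nuisance_names[j] for j in range(k)
                    if np.isclose(s[:, j].std(), 0.0)]
            raise ValueError(
                f"zero-variance nuisance feature(s) in reference group: {flat}"
            )
        design = np.column_stack([s, np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, c[ok], rcond=None)
        slopes[i] = coef[:k]
        intercepts[i] = coef[k]
        n_used[i] = n

    return NuisanceModel(
        feature_names, nuisance_names, slopes, intercepts, reference_group, n_used
    )


def correct_features(dataset: Dataset, model: NuisanceModel) -> Dataset:
    """Subtract the fitted nuisance effect from all subjects of all groups.

    Columns not named in the model are left untouched. A subject with a
    missing value in any model nuisance gets a missing corrected value
    (NaN propagates); imputation, if any, is the classifier's concern.
    """
    absent = [c for c in model.feature_names if c not in dataset.features.columns]
    absent += [c for c in model.nuisance_names if c not in dataset.nuisance.columns]
    if absent:
        raise ValueError(f"model columns absent from dataset: {absent}")
    effect = model.predict_nuisance_effect(dataset.nuisance)
    features = dataset.features.copy()
    features[list(model.feature_names)] = (
        features[list(model.feature_names)].to_numpy(dtype=float) - effect
    )
    return dataset.with_features(features)


def fit_and_correct(
    train: Dataset,
    apply_to: Dataset,
    feature_names: Sequence[str],
    nuisance_names: Sequence[str],
    reference_group: str,
) -> tuple[NuisanceModel, Dataset, Dataset]:
    """Fit on ``train``'s reference subjects; correct both datasets with it.

    The single model is learned from the training portion only, so test-set
    subjects never influence the fit (no information leakage), and is then
    applied to training and held-out subjects alike.
    """
    model = fit_nuisance_model(train, feature_names, nuisance_names, reference_group)
    return model, correct_features(train, model), correct_features(apply_to, model)
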