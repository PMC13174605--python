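"""Feature attribution for imputation models.

Permutation importance: the drop in held-out r² (squared Pearson between
prediction and truth — not 1 - SSE/SST, which differs for biased
predictions) after shuffling one feature's values, averaged over
``n_repeats`` seeded permutations.  First-K curves retrain the model on
the top-K ranked features to show how concentrated the signal is among
a protein's biological neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fidelity import _pearson
from .harmonize import ExpressionMatrix
from .impute_engine import ImputationModelSet, ModelSpec, SplitSpec, target_seed

DEFAULT_K_LIST = (1, 2, 3, 4, 5, 50, 100, 150, 200, 250, 300)


class ImportanceError(ValueError):
    """Raised for invalid attribution requests."""


def r_squared(pred: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation; 0.0 when the correlation is undefined."""
    r = _pearson(pred, truth)
    return 0.0 if np.isnan(r) else r * r


def permutation_importance(
    model,
    features_test: pd.DataFrame,
    target_test: pd.Series | np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out permutation importance for every feature column.

    For each feature, ``n_repeats`` seeded shuffles of that column (test
    set only; training data untouched) are scored and the mean and SD of
    the r² drop are reported, sorted by descending mean drop with SD and
    assay id as tie-breakers.
    """
    if len(features_test) < 3:
        raise ImportanceError("need at least 3 held-out samples")
    y = np.asarray(target_test, dtype=float)
    x = features_test.to_numpy(copy=True)
    base_r2 = r_squared(model.predict(x), y)
    rng = np.random.default_rng(seed)
    rows = []
    for j, feat in enumerate(features_test.columns):
        drops = np.empty(n_repeats)
        original = x[:, j].copy()
        for rep in range(n_repeats):
            x[:, j] = original[rng.permutation(len(original))]
            drops[rep] = base_r2 - r_squared(model.predict(x), y)
        x[:, j] = original
        rows.append((feat, drops.mean(), drops.std(ddof=0)))
    out = pd.DataFrame(rows, columns=["feature", "mean_drop", "sd_drop"])
    out["baseline_r2"] = base_r2
    out["n_repeats"] = n_repeats
    out = out.sort_values(
        ["mean_drop", "sd_drop", "feature"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return out


def rank_features(importance: pd.DataFrame) -> list[str]:
    """Feature ranking by mean drop (SD, then assay id break ties)."""
    return list(importance["feature"])


def first_k_curve(
    spec: ModelSpec,
    ranked_features: list[str],
    source: ExpressionMatrix,
    target: ExpressionMatrix,
    target_assay: str,
    split: SplitSpec,
    counterpart: ExpressionMatrix | None = None,
    counterpart_assay: str | None = None,
    k_list=DEFAULT_K_LIST,
    seed: int = 0,
) -> pd.DataFrame:
    """Retrain on the top-K features and score held-out performance.

    For each K the model is retrained on the training samples using only
    the top-K ranked features (taken in the source panel's column order,
    so K = all features reproduces the full model exactly) and evaluated
    on the test samples: ``model_r`` against the measured destination
    value and, when a counterpart matrix is given, ``cross_r`` against
    the measured source-platform counterpart.
    """
    n_features = len(ranked_features)
    ks = sorted({int(k) for k in k_list})
    clamped = [k for k in ks if k > n_features]
    if clamped:
        warnings.warn(
            f"K values {clamped} exceed the {n_features} available features; clamped",
            stacklevel=2,
        )
    ks = sorted({min(k, n_features) for k in ks if k >= 1})

    train = list(split.train_sample_ids)
    test = list(split.test_sample_ids)
    y_train = target.data.loc[train, target_assay].to_numpy()
    y_test = target.data.loc[test, target_assay].to_numpy()
    cross = None
    if counterpart is not None:
        if counterpart_assay is None:
            raise ImportanceError("counterpart matrix given without counterpart_assay")
        cross = counterpart.data.loc[test, counterpart_assay].to_numpy()

    panel_order = list(source.assay_ids)
    rows = []
    for k in ks:
        top = set(ranked_features[:k])
        cols = [a for a in panel_order if a in top]
        x_train = source.data.loc[train, cols].to_numpy()
        x_test = source.data.loc[test, cols].to_numpy()
        reg = spec.build(random_state=target_seed(seed, target_assay))
        reg.fit(x_train, y_train)
        pred = reg.predict(x_test)
        model_r = _pearson(pred, y_test)
        cross_r = _pearson(pred, cross) if cross is not None else np.nan
        rows.append((k, model_r, cross_r))
    return pd.DataFrame(rows, columns=["k", "model_r", "cross_r"])


def importance_for_target(
    models: ImputationModelSet,
    source: ExpressionMatrix,
    target: ExpressionMatrix,
    target_assay: str,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance of one fitted per-target model on the
    held-out split recorded in the model set."""
    if target_assay not in models.models:
        raise ImportanceError(f"no fitted model for target {target_assay!r}")
    test = list(models.split.test_sample_ids)
    features_test = source.data.loc[test, list(models.feature_ids)]
    target_test = target.data.loc[test, target_assay]
    return permutation_importance(
        models.models[target_assay], features_test, target_test, n_repeats=n_repeats, seed=seed
    )
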