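"""Per-target cross-platform imputation models.

For every assay on the destination platform, one histogram-binned
gradient-boosted tree regressor is fitted with the *entire* source-panel
measurement vector as features (never any destination-platform assay).
Models are trained on the training split only and applied to held-out
or external single-platform samples.  The two directions (aptamer->PEA
and PEA->aptamer) are configuration mirror images.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor

from .harmonize import SCALE_STANDARDIZED, ExpressionMatrix

BUNDLE_FORMAT_VERSION = 1

DIRECTION_A2B = "A2B"
DIRECTION_B2A = "B2A"


class ImputeError(ValueError):
    """Raised for invalid training or imputation requests."""


# ---------------------------------------------------------------------------
# Split and model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test partition of the paired samples."""

    train_sample_ids: tuple
    test_sample_ids: tuple
    seed: int
    train_fraction: float = 0.75

    def __post_init__(self) -> None:
        train, test = set(self.train_sample_ids), set(self.test_sample_ids)
        if train & test:
            raise ImputeError("train and test sample sets overlap")

    @property
    def all_sample_ids(self) -> tuple:
        return tuple(self.train_sample_ids) + tuple(self.test_sample_ids)


def split_samples(sample_ids, fraction: float = 0.75, seed: int = 0) -> SplitSpec:
    """Seeded uniform shuffle; train size = round(fraction * n)."""
    sample_ids = list(sample_ids)
    if len(sample_ids) < 4:
        raise ImputeError("need at least 4 samples to split")
    if not 0 < fraction < 1:
        raise ImputeError(f"train fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sample_ids))
    n_train = int(round(fraction * len(sample_ids)))
    n_train = min(max(n_train, 1), len(sample_ids) - 1)
    train = [sample_ids[i] for i in order[:n_train]]
    test = [sample_ids[i] for i in order[n_train:]]
    return SplitSpec(tuple(train), tuple(test), seed=seed, train_fraction=fraction)


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the per-target regressors.

    Defaults: 255 histogram bins, learning rate 0.1, at most 300 boosting
    iterations with early stopping on a 10% validation slice of the
    training split.
    """

    family: str = "hist_gradient_boosting"
    learning_rate: float = 0.1
    max_iter: int = 300
    max_bins: int = 255
    early_stopping: bool = True
    validation_fraction: float = 0.1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    def build(self, random_state: int) -> HistGradientBoostingRegressor:
        if self.family != "hist_gradient_boosting":
            raise ImputeError(f"unknown regressor family {self.family!r}")
        return HistGradientBoostingRegressor(
            learning_rate=self.learning_rate,
            max_iter=self.max_iter,
            max_bins=self.max_bins,
            early_stopping=self.early_stopping,
            validation_fraction=self.validation_fraction,
            random_state=random_state,
        )


def target_seed(global_seed: int, assay_id: str) -> int:
    """Stable per-target seed: CRC32 of the assay id XOR the global seed.

    Independent of which other targets are trained, so adding or removing
    targets never perturbs the remaining models.
    """
    return (zlib.crc32(assay_id.encode("utf8")) ^ (global_seed & 0xFFFFFFFF)) % (2**31)


# ---------------------------------------------------------------------------
# Training and imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationModelSet:
    """Direction-tagged collection of per-target fitted regressors."""

    direction: str
    source_platform: str
    dest_platform: str
    feature_ids: tuple
    models: dict  # target assay id -> fitted regressor
    split: SplitSpec
    spec: ModelSpec
    global_seed: int
    format_version: int = BUNDLE_FORMAT_VERSION

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.models)


def _check_training_inputs(source: ExpressionMatrix, target: ExpressionMatrix) -> None:
    if source.scale != SCALE_STANDARDIZED or target.scale != SCALE_STANDARDIZED:
        raise ImputeError("both matrices must be standardized before training")
    if list(source.sample_ids) != list(target.sample_ids):
        raise ImputeError("source and target matrices are not sample-aligned")
    if source.missing_mask.to_numpy().any() or target.missing_mask.to_numpy().any():
        raise ImputeError("matrices must be fully imputed (no missing values)")
    if not np.isfinite(source.data.to_numpy()).all() or not np.isfinite(
        target.data.to_numpy()
    ).all():
        raise ImputeError("non-finite values in training matrices")


def train_direction(
    source: ExpressionMatrix,
    target: ExpressionMatrix,
    split: SplitSpec,
    spec: ModelSpec | None = None,
    seed: int = 0,
    targets=None,
) -> ImputationModelSet:
    """Fit one regressor per destination assay on the training samples.

    Targets are mutually independent: the per-target RNG seed is derived
    only from (global seed, target assay id), so concurrent and
    sequential fitting produce identical results.  ``targets`` optionally
    restricts to a subset of destination assays for desk-scale runs.
    """
    spec = spec or ModelSpec()
    _check_training_inputs(source, target)
    absent = [s for s in split.train_sample_ids if s not in source.data.index]
    if absent:
        raise ImputeError(f"training samples missing from matrices: {absent[:5]}")
    target_ids = list(target.assay_ids) if targets is None else list(targets)
    unknown = [t for t in target_ids if t not in target.data.columns]
    if unknown:
        raise ImputeError(f"unknown target assays: {unknown[:5]}")

    x_train = source.data.loc[list(split.train_sample_ids)].to_numpy()
    models = {}
    for tid in target_ids:
        y_train = target.data.loc[list(split.train_sample_ids), tid].to_numpy()
        reg = spec.build(random_state=target_seed(seed, tid))
        reg.fit(x_train, y_train)
        models[tid] = reg

    direction = (
        DIRECTION_A2B if target.platform == "B_pea" else DIRECTION_B2A
    )
    return ImputationModelSet(
        direction=direction,
        source_platform=source.platform,
        dest_platform=target.platform,
        feature_ids=tuple(source.assay_ids),
        models=models,
        split=split,
        spec=spec,
        global_seed=seed,
    )


def impute(
    models: ImputationModelSet, source: ExpressionMatrix, samples=None
) -> ExpressionMatrix:
    """Predict the destination panel for the requested samples.

    The source matrix must contain every feature assay (standardized with
    the training-era scaler); extra assays are ignored.  Output is
    deterministic: same models + same input -> bitwise-identical values.
    """
    if source.scale != SCALE_STANDARDIZED:
        raise ImputeError("source matrix must be standardized")
    absent = [a for a in models.feature_ids if a not in source.data.columns]
    if absent:
        raise ImputeError(f"source panel missing feature assays: {absent[:5]}")
    if samples is None:
        samples = list(source.sample_ids)
    else:
        samples = list(samples)
        missing = [s for s in samples if s not in source.data.index]
        if missing:
            raise ImputeError(f"samples missing from source matrix: {missing[:5]}")
    x = source.data.loc[samples, list(models.feature_ids)].to_numpy()
    out = {tid: models.models[tid].predict(x) for tid in models.target_ids}
    df = pd.DataFrame(out, index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(df, platform=models.dest_platform, scale=SCALE_STANDARDIZED)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_models(models: ImputationModelSet, path) -> Path:
    """Write a model bundle: one joblib file per target plus a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": models.format_version,
        "direction": models.direction,
        "source_platform": models.source_platform,
        "dest_platform": models.dest_platform,
        "feature_ids": list(models.feature_ids),
        "target_ids": models.target_ids,
        "global_seed": models.global_seed,
        "spec": models.spec.to_dict(),
        "split": {
            "train_sample_ids": list(models.split.train_sample_ids),
            "test_sample_ids": list(models.split.test_sample_ids),
            "seed": models.split.seed,
            "train_fraction": models.split.train_fraction,
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for tid, reg in models.models.items():
        joblib.dump(reg, path / f"model_{tid}.joblib")
    return path


def load_models(path) -> ImputationModelSet:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ImputeError(f"no manifest.json in {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ImputeError(f"corrupted manifest in {path}: {exc}") from exc
    version = manifest.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ImputeError(
            f"model bundle format version {version} != supported {BUNDLE_FORMAT_VERSION}"
        )
    models = {}
    for tid in manifest["target_ids"]:
        model_path = path / f"model_{tid}.joblib"
        if not model_path.exists():
            raise ImputeError(f"missing model file for target {tid}")
        models[tid] = joblib.load(model_path)
    split = SplitSpec(
        tuple(manifest["split"]["train_sample_ids"]),
        tuple(manifest["split"]["test_sample_ids"]),
        seed=manifest["split"]["seed"],
        train_fraction=manifest["split"]["train_fraction"],
    )
    return ImputationModelSet(
        direction=manifest["direction"],
        source_platform=manifest["source_platform"],
        dest_platform=manifest["dest_platform"],
        feature_ids=tuple(manifest["feature_ids"]),
        models=models,
        split=split,
        spec=ModelSpec.from_dict(manifest["spec"]),
        global_seed=manifest["global_seed"],
        format_version=version,
    )
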