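"""Reading, lifting, transforming and QC of affinity-proteomics matrices.

Two platform families are handled: an aptamer platform reporting raw,
strictly positive relative-fluorescence-like values ("A_aptamer"), and a
PEA platform reporting NPX-like values that are already on a log2 scale
and carry below-LOD missingness ("B_pea").  The canonical processing
chain is

    aptamer:  read -> (lift between panel versions) -> log2 + z-score
    PEA:      read -> missingness QC -> duplicate resolution
                   -> feature-wise KNN imputation -> z-score

after which both matrices live on a common standardized scale and can be
matched protein-by-protein through the overlap table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PLATFORM_APTAMER = "A_aptamer"
PLATFORM_PEA = "B_pea"
PLATFORMS = (PLATFORM_APTAMER, PLATFORM_PEA)

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"
SCALE_STANDARDIZED = "standardized"
SCALES = (SCALE_RAW, SCALE_LOG2, SCALE_STANDARDIZED)

DEFAULT_NA_TOKEN = "NA"


class HarmonizeError(ValueError):
    """Raised for invalid matrices, tables or processing requests."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Sample x assay measurement grid.

    ``data`` is a float DataFrame indexed by sample id with assay ids as
    columns; missing measurements are NaN.  ``platform`` is one of
    :data:`PLATFORMS` and ``scale`` one of :data:`SCALES`.
    """

    data: pd.DataFrame
    platform: str
    scale: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise HarmonizeError(f"unknown platform {self.platform!r}")
        if self.scale not in SCALES:
            raise HarmonizeError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise HarmonizeError(f"duplicate sample ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise HarmonizeError(f"duplicate assay ids: {dups[:5]}")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the measurement is undefined."""
        return self.data.isna()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_assays(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.platform, self.scale)

    def to_tsv(self, path, na_token: str = DEFAULT_NA_TOKEN, sep: str = "\t") -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep=sep, na_rep=na_token)


@dataclass(frozen=True)
class Scaler:
    """Per-assay location/scale estimated on a designated sample subset.

    Uses the n-1 (sample) SD convention so that golden values in the test
    suite are reproducible.  Applying the scaler to held-out samples reuses
    the parameters estimated on ``fit_sample_ids`` and therefore cannot leak
    information from the held-out set.
    """

    means: pd.Series
    sds: pd.Series
    fit_sample_ids: tuple

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        missing = [a for a in data.columns if a not in self.means.index]
        if missing:
            raise HarmonizeError(f"scaler has no parameters for assays {missing[:5]}")
        return (data - self.means[data.columns]) / self.sds[data.columns]


def validate_assay_map(amap: pd.DataFrame) -> pd.DataFrame:
    """Check an assay<->protein mapping table.

    Required columns: ``assay_id``, ``platform``, ``protein_id``; an optional
    ``duplicate_rank`` column marks multi-reagent measurements of the same
    protein (suffix "_2/_3" style).  (assay_id, platform) must be unique.
    """
    required = {"assay_id", "platform", "protein_id"}
    missing = required - set(amap.columns)
    if missing:
        raise HarmonizeError(f"assay map missing columns {sorted(missing)}")
    if amap.duplicated(subset=["assay_id", "platform"]).any():
        raise HarmonizeError("assay map has duplicate (assay_id, platform) rows")
    bad = ~amap["platform"].isin(PLATFORMS)
    if bad.any():
        raise HarmonizeError(
            f"assay map has unknown platforms {sorted(amap.loc[bad, 'platform'].unique())}"
        )
    out = amap.copy()
    if "duplicate_rank" not in out.columns:
        out["duplicate_rank"] = 1
    return out


def validate_lift_table(lift: pd.DataFrame) -> pd.DataFrame:
    required = {"assay_id", "scale", "offset"}
    missing = required - set(lift.columns)
    if missing:
        raise HarmonizeError(f"lift table missing columns {sorted(missing)}")
    if lift["assay_id"].duplicated().any():
        raise HarmonizeError("lift table has duplicate assay ids")
    if (lift["scale"] <= 0).any():
        bad = lift.loc[lift["scale"] <= 0, "assay_id"].tolist()
        raise HarmonizeError(f"non-positive lift scale for assays {bad[:5]}")
    return lift


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_matrix(
    path,
    platform: str,
    scale: str,
    sep: str = "\t",
    na_token: str = DEFAULT_NA_TOKEN,
) -> ExpressionMatrix:
    """Read a wide sample x assay table (first column = sample_id)."""
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=[na_token], keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise HarmonizeError(f"non-numeric values in {path}: {exc}") from exc
    return ExpressionMatrix(df, platform=platform, scale=scale)


def read_assay_map(path, sep: str = "\t") -> pd.DataFrame:
    return validate_assay_map(pd.read_csv(path, sep=sep, dtype={"assay_id": str, "protein_id": str}))


def read_lift_table(path, sep: str = "\t") -> pd.DataFrame:
    return validate_lift_table(pd.read_csv(path, sep=sep, dtype={"assay_id": str}))


# ---------------------------------------------------------------------------
# Panel lifting and standardization
# ---------------------------------------------------------------------------

def lift_panel(matrix: ExpressionMatrix, lift: pd.DataFrame) -> ExpressionMatrix:
    """Apply per-assay linear panel-version transforms to raw values.

    value' = scale * value + offset.  Assays absent from the lift table are
    passed through unchanged with a warning; the missingness mask is
    untouched.
    """
    if matrix.scale != SCALE_RAW:
        raise HarmonizeError(f"lift_panel expects raw values, got scale={matrix.scale!r}")
    lift = validate_lift_table(lift)
    params = lift.set_index("assay_id")
    absent = [a for a in matrix.assay_ids if a not in params.index]
    if absent:
        warnings.warn(
            f"{len(absent)} assays absent from lift table are passed through unchanged",
            stacklevel=2,
        )
    scales = params["scale"].reindex(matrix.data.columns).fillna(1.0)
    offsets = params["offset"].reindex(matrix.data.columns).fillna(0.0)
    return ExpressionMatrix(matrix.data * scales + offsets, matrix.platform, matrix.scale)


def log2_standardize(
    matrix: ExpressionMatrix, fit_subset=None
) -> tuple[ExpressionMatrix, Scaler]:
    """log2-transform (raw input only) then z-score per assay.

    The mean and SD of each assay are estimated on ``fit_subset`` (default:
    all samples) and applied to the whole matrix; the returned
    :class:`Scaler` can be reused on held-out samples.  Input that is
    already standardized is rejected to guard against double transforms.
    """
    if matrix.scale == SCALE_STANDARDIZED:
        raise HarmonizeError("matrix is already standardized")
    values = matrix.data
    if matrix.scale == SCALE_RAW:
        nonpos = (values <= 0).to_numpy()
        if np.nansum(nonpos):
            bad = values.columns[(values <= 0).any(axis=0)].tolist()
            raise HarmonizeError(f"non-positive raw values in assays {bad[:5]}")
        values = np.log2(values)
    if fit_subset is None:
        fit_subset = list(values.index)
    else:
        fit_subset = list(fit_subset)
        absent = [s for s in fit_subset if s not in values.index]
        if absent:
            raise HarmonizeError(f"fit_subset samples not in matrix: {absent[:5]}")
    fit = values.loc[fit_subset]
    means = fit.mean(axis=0)
    sds = fit.std(axis=0, ddof=1)
    zero = sds[~(sds > 0)]
    if len(zero):
        raise HarmonizeError(f"zero-variance assays on fit subset: {list(zero.index)[:5]}")
    scaler = Scaler(means=means, sds=sds, fit_sample_ids=tuple(fit_subset))
    out = scaler.transform(values)
    return ExpressionMatrix(out, matrix.platform, SCALE_STANDARDIZED), scaler


def apply_scaler(matrix: ExpressionMatrix, scaler: Scaler) -> ExpressionMatrix:
    """Standardize with previously fitted parameters (log2 first if raw)."""
    if matrix.scale == SCALE_STANDARDIZED:
        raise HarmonizeError("matrix is already standardized")
    values = matrix.data
    if matrix.scale == SCALE_RAW:
        values = np.log2(values)
    return ExpressionMatrix(scaler.transform(values), matrix.platform, SCALE_STANDARDIZED)


# ---------------------------------------------------------------------------
# Missingness QC and feature-wise KNN imputation
# ---------------------------------------------------------------------------

def qc_missingness(matrix: ExpressionMatrix, threshold: float = 0.10) -> ExpressionMatrix:
    """Drop assays then samples with missing fraction strictly above threshold.

    The two passes run in a fixed order (assays first); sample missingness
    is evaluated over the retained assays only.  Boundary rule is strict
    ">" so an assay missing exactly 10% of samples is retained.
    """
    mask = matrix.missing_mask
    keep_assays = mask.mean(axis=0) <= threshold
    if not keep_assays.any():
        raise HarmonizeError("missingness QC removed every assay")
    data = matrix.data.loc[:, keep_assays[keep_assays].index]
    keep_samples = data.isna().mean(axis=1) <= threshold
    if not keep_samples.any():
        raise HarmonizeError("missingness QC removed every sample")
    data = data.loc[keep_samples[keep_samples].index]
    return ExpressionMatrix(data, matrix.platform, matrix.scale)


def _assay_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise assay distances: Euclidean over shared observed samples,
    rescaled by the shared-sample count (NaN-aware Euclidean convention):

        d(a, b) = sqrt( n_samples / n_shared * sum_shared (x_a - x_b)^2 )

    Pairs with no shared samples get an infinite distance.
    """
    n_samples, _ = values.shape
    obs = ~np.isnan(values)
    filled = np.where(obs, values, 0.0)
    sq = filled**2
    # sum over shared samples of (x - y)^2, computed with masked products
    cross = filled.T @ filled
    a_sq = sq.T @ obs.astype(float)
    shared = (obs.astype(float).T @ obs.astype(float))
    ssd = a_sq + a_sq.T - 2.0 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(shared > 0, n_samples * ssd / shared, np.inf)
    d2 = np.clip(d2, 0.0, None)  # guard tiny negatives from cancellation
    return np.sqrt(d2)


def knn_impute(matrix: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing entries with the unweighted mean of the k nearest assays.

    Neighbors are assays (feature-wise), matching the semantics of the
    KNN imputer commonly used for expression data; distance is NaN-aware
    Euclidean across samples.  For each hole, only neighbor assays observed
    at that sample donate; ties in distance break by assay column order.
    If no usable neighbor exists the assay's own observed mean is used.
    """
    if k < 1:
        raise HarmonizeError("k must be >= 1")
    data = matrix.data.copy()
    values = data.to_numpy()
    n_samples, n_assays = values.shape
    obs = ~np.isnan(values)
    if not (~obs).any():
        return matrix.copy()
    fully_missing = ~obs.any(axis=0)
    if fully_missing.any():
        bad = data.columns[fully_missing].tolist()
        raise HarmonizeError(f"assays with no observed values: {bad[:5]}")
    if k > n_assays - 1:
        warnings.warn(
            f"k={k} exceeds available neighbor assays ({n_assays - 1}); using all",
            stacklevel=2,
        )
        k = n_assays - 1
    dist = _assay_distance_matrix(values)
    np.fill_diagonal(dist, np.inf)
    # stable neighbor order: ascending distance, ties by column position
    order = np.argsort(dist, axis=1, kind="stable")
    col_means = np.nanmean(values, axis=0)
    filled = values.copy()
    holes = np.argwhere(~obs)
    for s, a in holes:
        donors = []
        for b in order[a]:
            if np.isinf(dist[a, b]):
                break
            if obs[s, b]:
                donors.append(values[s, b])
                if len(donors) == k:
                    break
        filled[s, a] = np.mean(donors) if donors else col_means[a]
    out = pd.DataFrame(filled, index=data.index, columns=data.columns)
    return ExpressionMatrix(out, matrix.platform, matrix.scale)


# ---------------------------------------------------------------------------
# Duplicate-assay resolution and cross-platform overlap
# ---------------------------------------------------------------------------

def resolve_duplicates(
    matrix: ExpressionMatrix,
    amap: pd.DataFrame,
    premask: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Keep one PEA assay per protein: the one with the lowest pre-imputation
    missing fraction (detectability proxy), ties broken by assay id.

    Aptamer-platform duplicates are deliberately retained as distinct
    reagent-specific measurements, so matrices from the aptamer platform
    pass through unchanged.
    """
    if matrix.platform != PLATFORM_PEA:
        return matrix.copy()
    amap = validate_assay_map(amap)
    sub = amap[(amap["platform"] == matrix.platform) & amap["assay_id"].isin(matrix.assay_ids)]
    if premask is None:
        premask = matrix.missing_mask
    miss_frac = premask.reindex(columns=matrix.assay_ids).mean(axis=0)
    keep: list[str] = []
    for _, grp in sub.groupby("protein_id", sort=True):
        assays = sorted(grp["assay_id"])
        best = min(assays, key=lambda a: (miss_frac.get(a, 0.0), a))
        keep.append(best)
    unmapped = [a for a in matrix.assay_ids if a not in set(sub["assay_id"])]
    keep_set = set(keep) | set(unmapped)
    cols = [a for a in matrix.assay_ids if a in keep_set]
    return ExpressionMatrix(matrix.data[cols], matrix.platform, matrix.scale)


def _pct_int(x: float) -> int:
    # printed coverage convention: one decimal first, then nearest integer
    # with ties-to-even (so 60.50 -> 60, 34.9 -> 35)
    return int(round(round(x, 1)))


def build_overlap(map_a: pd.DataFrame, map_b: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Match proteins measured on both platforms.

    Returns one row per (protein, aptamer assay) pair joined to the
    protein's single PEA assay, plus a summary with the distinct protein
    count and the integer percentage of each panel covered.
    """
    map_a = validate_assay_map(map_a)
    map_b = validate_assay_map(map_b)
    a = map_a[map_a["platform"] == PLATFORM_APTAMER]
    b = map_b[map_b["platform"] == PLATFORM_PEA]
    if b["protein_id"].duplicated().any():
        dups = b.loc[b["protein_id"].duplicated(), "protein_id"].unique().tolist()
        raise HarmonizeError(
            f"PEA map has multiple assays per protein (resolve duplicates first): {dups[:5]}"
        )
    merged = a.merge(b, on="protein_id", suffixes=("_A", "_B"))
    overlap = (
        merged[["protein_id", "assay_id_A", "assay_id_B"]]
        .sort_values(["protein_id", "assay_id_A"])
        .reset_index(drop=True)
    )
    n_proteins = overlap["protein_id"].nunique()
    summary = {
        "n_overlap_proteins": int(n_proteins),
        "n_assays_A": int(len(a)),
        "n_assays_B": int(len(b)),
        "coverage_pct_A": _pct_int(100.0 * n_proteins / len(a)) if len(a) else 0,
        "coverage_pct_B": _pct_int(100.0 * n_proteins / len(b)) if len(b) else 0,
    }
    return overlap, summary


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------

def harmonize_pair(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    amap: pd.DataFrame,
    lift: pd.DataFrame | None = None,
    fit_subset=None,
    qc_threshold: float = 0.10,
    knn_k: int = 10,
) -> tuple[ExpressionMatrix, ExpressionMatrix, Scaler, Scaler]:
    """Run the standard two-platform processing chain.

    Aptamer side: optional panel lift, then log2 + z-score.  PEA side:
    missingness QC, duplicate resolution on the pre-imputation mask,
    feature-wise KNN imputation, then z-score.  Scalers are fitted on
    ``fit_subset`` (e.g. the training split) and applied everywhere.

    Samples failing missingness QC on the PEA side are removed from both
    platforms so the returned matrices stay sample-aligned.
    """
    if mat_a.platform != PLATFORM_APTAMER or mat_b.platform != PLATFORM_PEA:
        raise HarmonizeError("harmonize_pair expects (aptamer, PEA) matrices")
    if lift is not None:
        mat_a = lift_panel(mat_a, lift)

    b_qc = qc_missingness(mat_b, threshold=qc_threshold)
    common = [s for s in mat_a.sample_ids if s in b_qc.data.index]
    if not common:
        raise HarmonizeError("no samples shared between the two platforms after QC")
    mat_a = ExpressionMatrix(mat_a.data.loc[common], mat_a.platform, mat_a.scale)
    b_qc = ExpressionMatrix(b_qc.data.loc[common], b_qc.platform, b_qc.scale)
    if fit_subset is not None:
        fit_subset = [s for s in fit_subset if s in common]

    a_std, scaler_a = log2_standardize(mat_a, fit_subset=fit_subset)

    b_dedup = resolve_duplicates(b_qc, amap, premask=b_qc.missing_mask)
    b_full = knn_impute(b_dedup, k=knn_k)
    b_std, scaler_b = log2_standardize(b_full, fit_subset=fit_subset)
    return a_std, b_std, scaler_a, scaler_b
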