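"""Concordance metrics and the 4-tier protein reliability system.

Three Pearson correlations are tracked per overlapping protein and
training direction:

baseline_r
    Between the two platforms' measured, standardized values on the
    training samples.
post_r
    Between the model-imputed destination value and the measured
    *source*-platform counterpart on held-out samples.
model_r
    Between the imputed and measured values of the same destination
    platform on held-out samples (defined for every destination assay,
    not just the overlap).

Tiers partition the signed (baseline_r, post_r) plane exhaustively:
tier 1 both >= 0.7; tier 4 both <= 0.1; else tier 2 if post_r >= 0.4,
tier 3 otherwise.  Signed correlations are used directly, so a protein
with a sign-distorting epitope artifact (negative r on both axes, the
PILRA phenomenon) lands in tier 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import ExpressionMatrix


class FidelityError(ValueError):
    """Raised for misaligned inputs to concordance computations."""


@dataclass(frozen=True)
class TierRules:
    """Thresholds of the tier partition.

    Boundary conventions: membership at t_high and t_mid uses >=, and at
    t_low uses <= (a correlation of exactly 0.1 on both axes is tier 4).
    """

    t_high: float = 0.7
    t_low: float = 0.1
    t_mid: float = 0.4

    def __post_init__(self) -> None:
        if not self.t_low < self.t_mid < self.t_high:
            raise FidelityError("tier thresholds must satisfy t_low < t_mid < t_high")

    def to_dict(self) -> dict:
        return {
            "t_high": self.t_high,
            "t_low": self.t_low,
            "t_mid": self.t_mid,
            "boundary": "tier1 >=t_high both; tier4 <=t_low both; tier2 post>=t_mid",
        }


# ---------------------------------------------------------------------------
# Pearson correlation with explicit undefined handling
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either vector has zero variance or n < 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise FidelityError("vectors of unequal length")
    if x.size < 2:
        return np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def _column_correlations(
    left: pd.DataFrame, right: pd.DataFrame, pairs: list[tuple[str, str]]
) -> list[float]:
    out = []
    for lcol, rcol in pairs:
        out.append(_pearson(left[lcol].to_numpy(), right[rcol].to_numpy()))
    return out


def _subset(matrix: ExpressionMatrix, samples) -> pd.DataFrame:
    if samples is None:
        return matrix.data
    samples = list(samples)
    missing = [s for s in samples if s not in matrix.data.index]
    if missing:
        raise FidelityError(f"samples missing from matrix: {missing[:5]}")
    return matrix.data.loc[samples]


def baseline_correlation(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    overlap: pd.DataFrame,
    samples=None,
) -> pd.DataFrame:
    """Per overlap row: Pearson r between the two measured platforms.

    A protein with several aptamer reagents yields one r per
    (aptamer, PEA) pair.  Zero-variance columns give NaN with a flag.
    """
    a = _subset(mat_a, samples)
    b = _subset(mat_b, samples)
    if list(a.index) != list(b.index):
        raise FidelityError("matrices are not sample-aligned")
    pairs = list(zip(overlap["assay_id_A"], overlap["assay_id_B"]))
    rs = _column_correlations(a, b, pairs)
    out = overlap[["protein_id", "assay_id_A", "assay_id_B"]].copy()
    out["baseline_r"] = rs
    out["baseline_defined"] = ~out["baseline_r"].isna()
    return out


def post_imputation_correlation(
    imputed: ExpressionMatrix,
    measured_counterpart: ExpressionMatrix,
    overlap: pd.DataFrame,
    samples=None,
    direction: str = "A2B",
) -> pd.DataFrame:
    """Pearson r between imputed destination and measured source counterpart.

    For direction A2B the imputed matrix holds PEA-panel predictions and
    the counterpart is the measured aptamer matrix (and symmetrically for
    B2A); evaluated on held-out samples only.
    """
    imp = _subset(imputed, samples)
    src = _subset(measured_counterpart, samples)
    if list(imp.index) != list(src.index):
        raise FidelityError("imputed and counterpart matrices are not sample-aligned")
    if direction == "A2B":
        pairs = [(b, a) for a, b in zip(overlap["assay_id_A"], overlap["assay_id_B"])]
    elif direction == "B2A":
        pairs = [(a, b) for a, b in zip(overlap["assay_id_A"], overlap["assay_id_B"])]
    else:
        raise FidelityError(f"unknown direction {direction!r}")
    rs = _column_correlations(imp, src, pairs)
    out = overlap[["protein_id", "assay_id_A", "assay_id_B"]].copy()
    out["post_r"] = rs
    out["post_defined"] = ~out["post_r"].isna()
    return out


def model_performance(
    imputed: ExpressionMatrix,
    measured_same_platform: ExpressionMatrix,
    samples=None,
) -> pd.Series:
    """Per destination assay: Pearson r of imputed vs measured values.

    Defined for every destination assay (overlapping or not); constant
    predictions give NaN.
    """
    imp = _subset(imputed, samples)
    meas = _subset(measured_same_platform, samples)
    if list(imp.index) != list(meas.index):
        raise FidelityError("matrices are not sample-aligned")
    shared = [a for a in imp.columns if a in meas.columns]
    rs = {a: _pearson(imp[a].to_numpy(), meas[a].to_numpy()) for a in shared}
    return pd.Series(rs, name="model_r")


def correlation_gain(baseline_r: float, post_r: float) -> tuple[float, float]:
    """(gain, magnitude gain) = (post - baseline, |post| - |baseline|).

    Undefined (NaN) inputs propagate to NaN outputs.
    """
    gain = post_r - baseline_r
    magnitude_gain = abs(post_r) - abs(baseline_r)
    return gain, magnitude_gain


def assign_tier(baseline_r: float, post_r: float, rules: TierRules | None = None) -> int:
    """Tier in {1, 2, 3, 4}; raises for undefined correlations.

    Signed values are used directly (no absolute value), an exhaustive
    mutually exclusive partition of [-1, 1]^2.
    """
    rules = rules or TierRules()
    if np.isnan(baseline_r) or np.isnan(post_r):
        raise FidelityError("cannot assign a tier to undefined correlations")
    if baseline_r >= rules.t_high and post_r >= rules.t_high:
        return 1
    if baseline_r <= rules.t_low and post_r <= rules.t_low:
        return 4
    if post_r >= rules.t_mid:
        return 2
    return 3


def assign_tiers(
    baseline_r: np.ndarray, post_r: np.ndarray, rules: TierRules | None = None
) -> np.ndarray:
    """Vectorized :func:`assign_tier`; NaN inputs give tier 0 (undefined)."""
    rules = rules or TierRules()
    b = np.asarray(baseline_r, dtype=float)
    p = np.asarray(post_r, dtype=float)
    out = np.full(b.shape, 3, dtype=int)
    out[p >= rules.t_mid] = 2
    out[(b <= rules.t_low) & (p <= rules.t_low)] = 4
    out[(b >= rules.t_high) & (p >= rules.t_high)] = 1
    out[np.isnan(b) | np.isnan(p)] = 0
    return out


# ---------------------------------------------------------------------------
# Record assembly and reporting
# ---------------------------------------------------------------------------

def make_fidelity_records(
    baseline: pd.DataFrame,
    post: pd.DataFrame,
    model_r: pd.Series,
    direction: str,
    rules: TierRules | None = None,
) -> pd.DataFrame:
    """Join the three concordance tables into per-pair fidelity records.

    Rows with an undefined baseline or post correlation get no tier
    (tier 0) and are excluded from tier statistics downstream.
    """
    rules = rules or TierRules()
    rec = baseline.merge(
        post[["protein_id", "assay_id_A", "assay_id_B", "post_r"]],
        on=["protein_id", "assay_id_A", "assay_id_B"],
        how="inner",
    )
    dest_col = "assay_id_B" if direction == "A2B" else "assay_id_A"
    rec["model_r"] = rec[dest_col].map(model_r)
    rec["gain"] = rec["post_r"] - rec["baseline_r"]
    rec["magnitude_gain"] = rec["post_r"].abs() - rec["baseline_r"].abs()
    rec["tier"] = assign_tiers(rec["baseline_r"].to_numpy(), rec["post_r"].to_numpy(), rules)
    rec["direction"] = direction
    return rec


def protein_rollup(records: pd.DataFrame) -> pd.DataFrame:
    """Protein-level records: for multi-aptamer proteins keep the pair
    with the highest post-imputation correlation."""
    defined = records[records["tier"] != 0]
    idx = defined.groupby("protein_id")["post_r"].idxmax()
    return defined.loc[idx].sort_values("protein_id").reset_index(drop=True)


def consensus_tiers(records_dir1: pd.DataFrame, records_dir2: pd.DataFrame) -> dict:
    """Bidirectional tier agreement summary on protein-level records."""
    r1 = protein_rollup(records_dir1).set_index("protein_id")["tier"]
    r2 = protein_rollup(records_dir2).set_index("protein_id")["tier"]
    if set(r1.index) != set(r2.index):
        raise FidelityError("protein sets differ between directions")
    r2 = r2[r1.index]
    agree = r1 == r2
    per_tier = {}
    for tier in (1, 2, 3, 4):
        in_tier = r1 == tier
        n = int(in_tier.sum())
        per_tier[tier] = {
            "n": n,
            "pct_agree": float(100.0 * (agree & in_tier).sum() / n) if n else np.nan,
        }
    table = pd.DataFrame(
        {"tier_dir1": r1, "tier_dir2": r2, "agree": agree}
    ).reset_index()
    return {
        "table": table,
        "overall_pct_agree": float(100.0 * agree.mean()),
        "per_tier": per_tier,
    }


def tier_report(
    records: pd.DataFrame,
    tsv_path=None,
    json_path=None,
    rules: TierRules | None = None,
) -> dict:
    """Per-record TSV plus a tier-distribution summary (counts/fractions).

    Records with undefined correlations (tier 0) are reported in the TSV
    but excluded from the distribution.
    """
    rules = rules or TierRules()
    defined = records[records["tier"] != 0]
    counts = defined["tier"].value_counts().reindex([1, 2, 3, 4], fill_value=0)
    total = int(counts.sum())
    summary = {
        "n_records": int(len(records)),
        "n_tiered": total,
        "counts": {int(t): int(c) for t, c in counts.items()},
        "fractions": {
            int(t): (float(c) / total if total else np.nan) for t, c in counts.items()
        },
        "rules": rules.to_dict(),
    }
    if tsv_path is not None:
        records.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summary, indent=1))
    return summary
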