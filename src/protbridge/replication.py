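"""Tier-informed downstream analyses.

Two replication-style analyses mirror how single-platform cohorts use
(imputed) proteomes:

* a penalized linear model of a continuous outcome on the protein panel
  with unpenalized covariates (age, sex, group), tuned by 10-fold
  cross-validation and evaluated by held-out squared Pearson r², with
  per-protein permutation importance; and
* a proteome-wide proportional-hazards scan: one Cox model per protein
  (standardized to mean 0, SD 1), covariate-adjusted, with Wald CIs and
  Bonferroni correction over the converged fits.

The elastic net's unpenalized covariate block is profiled out exactly:
for fixed protein coefficients the covariate solution is OLS, so the
penalized problem reduces (Frisch-Waugh) to a plain elastic net on
covariate-residualized outcome and proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sklearn.impute import KNNImputer
from sklearn.linear_model import ElasticNet, ElasticNetCV

from .fidelity import _pearson
from .importance import r_squared

DEFAULT_L1_RATIOS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


class ReplicationError(ValueError):
    """Raised for invalid replication-analysis inputs."""


# ---------------------------------------------------------------------------
# Penalized continuous-outcome model with unpenalized covariates
# ---------------------------------------------------------------------------

@dataclass
class PenalizedLinearResult:
    protein_coefs: pd.Series
    covariate_coefs: pd.Series
    intercept: float
    l1_ratio: float
    alpha: float
    r2: float
    importance: pd.DataFrame
    dropped_proteins: list = field(default_factory=list)

    def predict(self, proteins: pd.DataFrame, covariates: pd.DataFrame) -> np.ndarray:
        x = proteins[self.protein_coefs.index].to_numpy()
        c = covariates[self.covariate_coefs.index].to_numpy()
        return (
            self.intercept
            + x @ self.protein_coefs.to_numpy()
            + c @ self.covariate_coefs.to_numpy()
        )


def _residualize(
    c_train: np.ndarray, targets: list[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Project out the covariate span (with intercept); returns the
    augmented covariate design and residualized targets."""
    ones = np.ones((c_train.shape[0], 1))
    design = np.hstack([ones, c_train])
    coefs, *_ = np.linalg.lstsq(design, np.column_stack(targets), rcond=None)
    resid = np.column_stack(targets) - design @ coefs
    return design, [resid[:, i] for i in range(resid.shape[1])]


def fit_penalized_linear(
    proteins: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: pd.Series,
    cv_folds: int = 10,
    eval_split: float = 0.8,
    seed: int = 0,
    l1_ratios=DEFAULT_L1_RATIOS,
    n_alphas: int = 50,
    importance_repeats: int = 5,
    tune_on_full: bool = True,
) -> PenalizedLinearResult:
    """Elastic net of a continuous outcome on proteins + unpenalized covariates.

    Samples with a missing outcome are removed; missing covariates raise
    (impute them first).  The mixing parameter and penalty strength are
    tuned by ``cv_folds``-fold cross-validation on the full analytic set
    (as cohort analyses typically do; set ``tune_on_full=False`` for a
    strict no-leakage mode tuning on the training split only), the final
    model is refitted on an ``eval_split`` fraction and scored by squared
    Pearson r² on the remaining hold-out, where per-protein permutation
    importance is also computed.
    """
    if not proteins.index.equals(covariates.index) or not proteins.index.equals(
        outcome.index
    ):
        raise ReplicationError("proteins, covariates and outcome must share an index")
    keep = outcome.notna()
    proteins, covariates, outcome = proteins[keep], covariates[keep], outcome[keep]
    if covariates.isna().any().any():
        raise ReplicationError("missing covariate values: impute covariates first")
    if proteins.isna().any().any():
        raise ReplicationError("missing protein values: impute the matrix first")

    variances = proteins.var(axis=0, ddof=1)
    dropped = list(variances[~(variances > 0)].index)
    if dropped:
        warnings.warn(f"dropping zero-variance proteins: {dropped[:5]}", stacklevel=2)
        proteins = proteins.drop(columns=dropped)

    rng = np.random.default_rng(seed)
    n = len(outcome)
    order = rng.permutation(n)
    n_train = int(round(eval_split * n))
    train_idx, test_idx = order[:n_train], order[n_train:]
    if len(test_idx) < 3:
        raise ReplicationError("hold-out evaluation set too small")

    x = proteins.to_numpy()
    c = covariates.to_numpy(dtype=float)
    y = outcome.to_numpy(dtype=float)

    # -- tune (alpha, l1_ratio) on covariate-residualized data
    tune_rows = slice(None) if tune_on_full else train_idx
    _, (y_res, *_) = _residualize(c[tune_rows], [y[tune_rows]])
    _, x_res_cols = _residualize(c[tune_rows], [x[tune_rows, j] for j in range(x.shape[1])])
    x_res = np.column_stack(x_res_cols)
    cv = ElasticNetCV(
        l1_ratio=list(l1_ratios),
        alphas=n_alphas,
        cv=cv_folds,
        random_state=int(rng.integers(2**31)),
        max_iter=5000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv.fit(x_res, y_res)
    l1_ratio, alpha = float(cv.l1_ratio_), float(cv.alpha_)

    # -- final fit on the training split with the tuned parameters
    result = _fit_en_unpenalized(
        x[train_idx], c[train_idx], y[train_idx], alpha=alpha, l1_ratio=l1_ratio
    )
    beta, gamma, intercept = result

    protein_coefs = pd.Series(beta, index=proteins.columns, name="coef")
    covariate_coefs = pd.Series(gamma, index=covariates.columns, name="coef")

    pred_test = intercept + x[test_idx] @ beta + c[test_idx] @ gamma
    r2 = r_squared(pred_test, y[test_idx])

    # -- permutation importance of each protein on the hold-out
    imp_rng = np.random.default_rng((seed, 1))
    rows = []
    x_test = x[test_idx].copy()
    for j, prot in enumerate(proteins.columns):
        drops = np.empty(importance_repeats)
        original = x_test[:, j].copy()
        for rep in range(importance_repeats):
            x_test[:, j] = original[imp_rng.permutation(len(original))]
            perm_pred = intercept + x_test @ beta + c[test_idx] @ gamma
            drops[rep] = r2 - r_squared(perm_pred, y[test_idx])
        x_test[:, j] = original
        rows.append((prot, drops.mean(), drops.std(ddof=0)))
    importance = (
        pd.DataFrame(rows, columns=["protein_id", "mean_drop", "sd_drop"])
        .sort_values(["mean_drop", "sd_drop", "protein_id"], ascending=[False, False, True])
        .reset_index(drop=True)
    )

    return PenalizedLinearResult(
        protein_coefs=protein_coefs,
        covariate_coefs=covariate_coefs,
        intercept=float(intercept),
        l1_ratio=l1_ratio,
        alpha=alpha,
        r2=float(r2),
        importance=importance,
        dropped_proteins=dropped,
    )


def _fit_en_unpenalized(
    x: np.ndarray, c: np.ndarray, y: np.ndarray, alpha: float, l1_ratio: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact elastic net with an unpenalized covariate block.

    Residualize y and X on [1, C], solve the elastic net on the
    residuals, then recover the covariate coefficients by OLS of the
    protein-adjusted outcome on [1, C].
    """
    design, (y_res, *_) = _residualize(c, [y])
    _, x_res_cols = _residualize(c, [x[:, j] for j in range(x.shape[1])])
    x_res = np.column_stack(x_res_cols) if x_res_cols else np.empty((len(y), 0))
    if x_res.shape[1]:
        en = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            en.fit(x_res, y_res)
        beta = en.coef_
    else:
        beta = np.empty(0)
    adj = y - x @ beta
    cov_coefs, *_ = np.linalg.lstsq(design, adj, rcond=None)
    intercept, gamma = cov_coefs[0], cov_coefs[1:]
    return beta, gamma, float(intercept)


# ---------------------------------------------------------------------------
# Proteome-wide proportional-hazards scan
# ---------------------------------------------------------------------------

def ph_scan(
    proteins: pd.DataFrame,
    covariates: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    covariate_knn_k: int = 10,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """One Cox proportional-hazards fit per protein, covariate-adjusted.

    Each protein is standardized to mean 0, SD 1 before entering its
    model, so hazard ratios are per 1 SD of (log-scale) protein level.
    Missing covariates are KNN-imputed (k=10) beforehand; ties use the
    Breslow approximation (lifelines default).  Non-converging fits are
    flagged and excluded from the Bonferroni denominator.
    """
    if adjust not in ("bonferroni", "none"):
        raise ReplicationError(f"unknown adjustment {adjust!r}")
    idx = proteins.index
    for other in (covariates.index, time.index, event.index):
        if not idx.equals(other):
            raise ReplicationError("inputs must share a sample index")
    if (time <= 0).any():
        raise ReplicationError("non-positive follow-up times")
    if event.sum() == 0:
        raise ReplicationError("no events observed")

    cov = covariates.astype(float)
    if cov.isna().any().any():
        imputer = KNNImputer(n_neighbors=covariate_knn_k)
        cov = pd.DataFrame(imputer.fit_transform(cov), index=cov.index, columns=cov.columns)

    rows = []
    for prot in proteins.columns:
        values = proteins[prot].astype(float)
        sd = values.std(ddof=1)
        if not sd > 0:
            rows.append((prot, np.nan, np.nan, np.nan, np.nan, False))
            continue
        z = (values - values.mean()) / sd
        df = cov.copy()
        df["_protein"] = z
        df["_time"] = time.astype(float)
        df["_event"] = event.astype(int)
        fitter = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(df, duration_col="_time", event_col="_event")
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            rows.append((prot, np.nan, np.nan, np.nan, np.nan, False))
            continue
        coef = fitter.params_["_protein"]
        se = fitter.standard_errors_["_protein"]
        zscore = coef / se
        p = 2.0 * stats.norm.sf(abs(zscore))
        lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
        rows.append((prot, np.exp(coef), np.exp(lo), np.exp(hi), p, True))

    out = pd.DataFrame(
        rows, columns=["protein_id", "hr", "ci_low", "ci_high", "p", "converged"]
    )
    n_tests = int(out["converged"].sum())
    if not out["converged"].all():
        warnings.warn(
            f"{len(out) - n_tests} protein models failed to converge; "
            "excluded from the adjustment denominator",
            stacklevel=2,
        )
    if adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p"] * n_tests, 1.0)
    else:
        out["p_adjusted"] = out["p"]
    out.attrs["n_tests"] = n_tests
    return out


# ---------------------------------------------------------------------------
# Cross-cohort importance agreement
# ---------------------------------------------------------------------------

def compare_importance(
    results_a: pd.DataFrame, results_b: pd.DataFrame, top_k: int = 5
) -> dict:
    """Agreement between two cohorts' protein-importance tables.

    Returns the Spearman rank correlation of mean importance over the
    shared proteins and the overlap fraction of the top-k sets.
    """
    key = "protein_id" if "protein_id" in results_a.columns else "feature"
    a = results_a.set_index(key)["mean_drop"]
    b = results_b.set_index(key)["mean_drop"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ReplicationError("no shared proteins between importance tables")
    a, b = a[shared], b[shared]
    if len(shared) < 2 or a.nunique() == 1 or b.nunique() == 1:
        rank_corr = np.nan
    else:
        rank_corr = float(stats.spearmanr(a, b).statistic)
    k = min(top_k, len(shared))
    top_a = set(a.sort_values(ascending=False).index[:k])
    top_b = set(b.sort_values(ascending=False).index[:k])
    return {
        "n_shared": int(len(shared)),
        "rank_correlation": rank_corr,
        "top_k": k,
        "top_k_overlap": float(len(top_a & top_b) / k) if k else np.nan,
    }
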