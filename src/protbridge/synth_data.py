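"""Paired two-platform proteomic simulator with known latent truth.

Generates the statistical structure the bridging framework assumes: a
latent concentration matrix with block-correlated "biological neighbor"
proteins, two distorted platform readouts of it, and linked continuous
and time-to-event phenotypes.  Each protein belongs to one fidelity
class that determines how the two platforms distort its latent signal:

faithful
    Positive affine readout plus small noise on both platforms; the two
    platforms agree and the protein should land in tier 1.
recoverable
    The aptamer platform applies a variance-normalized monotone cubic
    (x + 0.4 x^3) / sqrt(5.8) plus small noise, while the PEA readout
    carries heavy additive noise.  Baseline concordance is modest but the
    imputation model, given the whole aptamer panel, can denoise the PEA
    side; these proteins should gain correlation and land in tier 2.
ambivalent
    Heavy noise on both platforms; denoising one side still leaves the
    other side's noise in the concordance metric, so the post-imputation
    correlation stays low (tier 3).
irreconcilable
    Either off-target (the aptamer assay reads an unrelated protein's
    latent from a different correlation block) or an epitope artifact
    (a binding-site variant shifts carriers in opposite directions on
    the two platforms, producing a negative baseline correlation, as
    observed for PILRA-like proteins).  Neither is recoverable: tier 4.

The PEA platform additionally left-censors values below a per-assay
LOD quantile to missing, before any standardization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import (
    DEFAULT_NA_TOKEN,
    PLATFORM_APTAMER,
    PLATFORM_PEA,
    SCALE_LOG2,
    SCALE_RAW,
    ExpressionMatrix,
)

CLASSES = ("faithful", "recoverable", "ambivalent", "irreconcilable")

# cubic monotone distortion, scaled to unit variance for a standard normal
# input: Var(x + 0.4 x^3) = 1 + 0.8 E[x^4] + 0.16 E[x^6] = 5.8
_CUBIC_NORM = np.sqrt(5.8)


class SimConfigError(ValueError):
    """Raised for inconsistent simulator configurations."""


def _cubic(x: np.ndarray) -> np.ndarray:
    return (x + 0.4 * x**3) / _CUBIC_NORM


@dataclass
class SimConfig:
    """Study conditions for one simulated paired-platform dataset.

    Noise SDs are on the standardized latent scale (latent variance 1).
    ``noise_sd_by_class`` maps class -> SD, or class -> (SD on platform A,
    SD on platform B) where the two platforms differ.  The recoverable
    class is deliberately asymmetric: the distortion sits on the aptamer
    side and the heavy noise on the PEA side, which is what makes the
    class recoverable by panel-wide imputation.
    """

    n_samples: int = 2000
    n_proteins: int = 120
    block_sizes: tuple | None = None  # default: blocks of 10
    within_block_corr: float = 0.6
    class_proportions: dict = field(
        default_factory=lambda: {
            "faithful": 0.20,
            "recoverable": 0.35,
            "ambivalent": 0.25,
            "irreconcilable": 0.20,
        }
    )
    noise_sd_by_class: dict = field(
        default_factory=lambda: {
            "faithful": 0.3,
            "recoverable": (0.35, 1.4),
            "ambivalent": 2.0,
            "irreconcilable": 0.3,
        }
    )
    lod_quantile: float = 0.05
    epitope_effect_size: float = 3.5
    epitope_carrier_freq: float = 0.3
    epitope_fraction: float = 0.5  # share of irreconcilable proteins
    phenotype_sparsity: int = 10
    effect_sizes: tuple = (0.5,)
    survival_effect_sizes: tuple = (np.log(1.5),)
    phenotype_noise_sd: float = 1.0
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.02
    confounded_covariates: bool = False
    n_duplicate_aptamers: int = 0
    n_duplicate_pea: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_sizes is None:
            if self.n_proteins % 10 == 0:
                self.block_sizes = tuple([10] * (self.n_proteins // 10))
            else:
                self.block_sizes = tuple([self.n_proteins])
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if sum(self.block_sizes) != self.n_proteins:
            raise SimConfigError(
                f"block_sizes sum {sum(self.block_sizes)} != n_proteins {self.n_proteins}"
            )
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise SimConfigError("class_proportions must sum to 1")
        if set(self.class_proportions) != set(CLASSES):
            raise SimConfigError(f"class_proportions keys must be {CLASSES}")
        for cls, sd in self.noise_sd_by_class.items():
            sds = np.atleast_1d(np.asarray(sd, dtype=float))
            if (sds <= 0).any():
                raise SimConfigError(f"noise SD for class {cls!r} must be > 0")
        if not 0 <= self.lod_quantile < 1:
            raise SimConfigError("lod_quantile must be in [0, 1)")
        if self.phenotype_sparsity > self.n_proteins:
            raise SimConfigError("phenotype_sparsity exceeds n_proteins")
        if not 0 <= self.censoring_rate < 1:
            raise SimConfigError("censoring_rate must be in [0, 1)")
        m = max(self.block_sizes)
        if self.within_block_corr >= 1 or (
            m > 1 and self.within_block_corr < -1.0 / (m - 1)
        ):
            raise SimConfigError(
                f"within_block_corr {self.within_block_corr} gives a non-PSD covariance"
            )

    def noise_sds(self, cls: str) -> tuple[float, float]:
        """(SD on platform A, SD on platform B) for a class."""
        sd = self.noise_sd_by_class[cls]
        if np.ndim(sd) == 0:
            return float(sd), float(sd)
        a, b = sd
        return float(a), float(b)


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    latent: pd.DataFrame  # samples x proteins, ~N(0, 1) each
    class_labels: pd.Series  # protein -> class
    subtype_labels: pd.Series  # protein -> '', 'off_target' or 'epitope'
    distortion_params: pd.DataFrame  # per protein: affine scale/offset per platform etc.
    off_target_source: pd.Series  # protein -> source protein id ('' if none)
    genotypes: pd.DataFrame  # samples x epitope proteins, 0/1 carriers
    phenotype_coefs: pd.Series  # protein -> continuous-outcome coefficient
    survival_coefs: pd.Series  # protein -> log hazard ratio per SD
    config: SimConfig

    @property
    def protein_ids(self) -> list[str]:
        return list(self.latent.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.latent.index)


def _class_counts(config: SimConfig) -> dict[str, int]:
    """Largest-remainder apportionment of proteins to classes."""
    p = config.n_proteins
    raw = {c: config.class_proportions[c] * p for c in CLASSES}
    counts = {c: int(np.floor(raw[c])) for c in CLASSES}
    short = p - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def simulate_latent(config: SimConfig) -> SimTruth:
    """Draw the latent matrix and fix all per-protein ground-truth labels.

    The latent is zero-mean unit-variance multivariate normal with
    block-exchangeable correlation (``within_block_corr`` inside each
    block, 0 across blocks); reproducible under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_proteins
    rho = config.within_block_corr

    cols = []
    for size in config.block_sizes:
        if rho >= 0:
            shared = rng.standard_normal((n, 1))
            eps = rng.standard_normal((n, size))
            cols.append(np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps)
        else:
            cov = np.full((size, size), rho)
            np.fill_diagonal(cov, 1.0)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise SimConfigError("non-PSD within-block covariance") from exc
            cols.append(rng.standard_normal((n, size)) @ chol.T)
    latent = np.hstack(cols)

    width = max(4, len(str(p)))
    protein_ids = [f"P{i + 1:0{width}d}" for i in range(p)]
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    latent = pd.DataFrame(latent, index=sample_ids, columns=protein_ids)

    counts = _class_counts(config)
    labels = np.concatenate([[c] * counts[c] for c in CLASSES])
    labels = pd.Series(rng.permutation(labels), index=protein_ids, name="class")

    block_of = np.repeat(np.arange(len(config.block_sizes)), config.block_sizes)
    block_of = pd.Series(block_of, index=protein_ids)

    # irreconcilable subtypes: a fixed fraction are epitope artifacts,
    # the rest read an off-target protein from a different block
    irr = [pid for pid in protein_ids if labels[pid] == "irreconcilable"]
    n_epitope = int(round(config.epitope_fraction * len(irr)))
    subtype = pd.Series("", index=protein_ids, name="subtype")
    epitope_ids = irr[:n_epitope]
    off_target_ids = irr[n_epitope:]
    subtype[epitope_ids] = "epitope"
    subtype[off_target_ids] = "off_target"

    off_source = pd.Series("", index=protein_ids, name="off_target_source")
    for pid in off_target_ids:
        candidates = [q for q in protein_ids if block_of[q] != block_of[pid]]
        if not candidates:
            candidates = [q for q in protein_ids if q != pid]
        off_source[pid] = candidates[rng.integers(len(candidates))]

    genotypes = pd.DataFrame(
        rng.binomial(1, config.epitope_carrier_freq, size=(n, len(epitope_ids))),
        index=sample_ids,
        columns=epitope_ids,
        dtype=float,
    )

    # faithful-class positive affine readout parameters (shared by both
    # platforms up to independent noise)
    distortion = pd.DataFrame(
        {
            "affine_scale": rng.uniform(0.8, 1.2, size=p),
            "affine_offset": rng.uniform(-0.5, 0.5, size=p),
        },
        index=protein_ids,
    )
    distortion["class"] = labels
    distortion["subtype"] = subtype

    # sparse phenotype coefficients, stratified across classes so causal
    # proteins span the fidelity spectrum
    order = np.concatenate(
        [rng.permutation([pid for pid in protein_ids if labels[pid] == c]) for c in CLASSES]
    )
    take = max(1, config.phenotype_sparsity) if config.phenotype_sparsity else 0
    causal: list[str] = []
    if take:
        per_class = {
            c: [pid for pid in order if labels[pid] == c] for c in CLASSES
        }
        quota = {
            c: int(round(config.phenotype_sparsity * config.class_proportions[c]))
            for c in CLASSES
        }
        while sum(quota.values()) < config.phenotype_sparsity:
            quota["recoverable"] += 1
        for c in CLASSES:
            causal.extend(per_class[c][: quota[c]])
        causal = causal[: config.phenotype_sparsity]

    signs = rng.choice([-1.0, 1.0], size=len(causal))
    effects = np.resize(np.asarray(config.effect_sizes, dtype=float), len(causal))
    phen = pd.Series(0.0, index=protein_ids, name="phenotype_coef")
    phen[causal] = signs * effects

    surv_effects = np.resize(
        np.asarray(config.survival_effect_sizes, dtype=float), len(causal)
    )
    surv = pd.Series(0.0, index=protein_ids, name="survival_coef")
    surv[causal] = surv_effects

    return SimTruth(
        latent=latent,
        class_labels=labels,
        subtype_labels=subtype,
        distortion_params=distortion,
        off_target_source=off_source,
        genotypes=genotypes,
        phenotype_coefs=phen,
        survival_coefs=surv,
        config=config,
    )


def _measure_signal(truth: SimTruth, platform: str, rng: np.random.Generator) -> pd.DataFrame:
    """Per-protein measurement on the standardized latent scale."""
    config = truth.config
    latent = truth.latent
    n = latent.shape[0]
    out = {}
    for pid in truth.protein_ids:
        cls = truth.class_labels[pid]
        sd_a, sd_b = config.noise_sds(cls)
        sd = sd_a if platform == PLATFORM_APTAMER else sd_b
        noise = sd * rng.standard_normal(n)
        x = latent[pid].to_numpy()
        if cls == "faithful":
            a = truth.distortion_params.loc[pid, "affine_scale"]
            b = truth.distortion_params.loc[pid, "affine_offset"]
            signal = a * x + b
        elif cls == "recoverable":
            # monotone cubic distortion on the aptamer platform only
            signal = _cubic(x) if platform == PLATFORM_APTAMER else x
        elif cls == "ambivalent":
            signal = x
        elif cls == "irreconcilable":
            if truth.subtype_labels[pid] == "off_target":
                # the aptamer reagent binds an unrelated protein
                if platform == PLATFORM_APTAMER:
                    signal = latent[truth.off_target_source[pid]].to_numpy()
                else:
                    signal = x
            else:  # epitope artifact: opposite shifts for variant carriers
                g = truth.genotypes[pid].to_numpy()
                shift = config.epitope_effect_size * g
                signal = x + shift if platform == PLATFORM_APTAMER else x - shift
        else:  # pragma: no cover - guarded by SimConfig validation
            raise SimConfigError(f"unknown class label {cls!r}")
        out[pid] = signal + noise
    return pd.DataFrame(out, index=latent.index)


def measure_platform(truth: SimTruth, platform: str, config: SimConfig | None = None) -> ExpressionMatrix:
    """Produce one platform's readout of the latent truth.

    The aptamer platform returns strictly positive RFU-like raw values
    (2**(signal + 10)); the PEA platform returns NPX-like log2-scale
    values with sub-LOD entries (per-assay ``lod_quantile``) set to
    missing.  The two platforms use distinct, seed-derived noise streams.
    """
    config = config or truth.config
    if platform not in (PLATFORM_APTAMER, PLATFORM_PEA):
        raise ValueError(f"unknown platform {platform!r}")
    stream = 1 if platform == PLATFORM_APTAMER else 2
    rng = np.random.default_rng((config.seed, stream))
    signal = _measure_signal(truth, platform, rng)

    suffix = "_A" if platform == PLATFORM_APTAMER else "_B"
    signal.columns = [pid + suffix for pid in signal.columns]

    # optional duplicate reagents (extra independent readouts)
    n_dup = (
        config.n_duplicate_aptamers
        if platform == PLATFORM_APTAMER
        else config.n_duplicate_pea
    )
    if n_dup:
        dup_ids = truth.protein_ids[:n_dup]
        dup_signal = _measure_signal(truth, platform, rng)
        for pid in dup_ids:
            signal[f"{pid}_2{suffix}"] = dup_signal[pid]

    if platform == PLATFORM_APTAMER:
        rfu = np.power(2.0, signal + 10.0)
        return ExpressionMatrix(rfu, platform=platform, scale=SCALE_RAW)

    if config.lod_quantile > 0:
        lod = signal.quantile(config.lod_quantile, axis=0)
        signal = signal.mask(signal.lt(lod, axis=1))
    return ExpressionMatrix(signal, platform=platform, scale=SCALE_LOG2)


def assay_maps(truth: SimTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assay<->protein mapping tables matching :func:`measure_platform`."""
    config = truth.config
    rows_a, rows_b = [], []
    for pid in truth.protein_ids:
        rows_a.append((pid + "_A", PLATFORM_APTAMER, pid, 1))
        rows_b.append((pid + "_B", PLATFORM_PEA, pid, 1))
    for pid in truth.protein_ids[: config.n_duplicate_aptamers]:
        rows_a.append((f"{pid}_2_A", PLATFORM_APTAMER, pid, 2))
    for pid in truth.protein_ids[: config.n_duplicate_pea]:
        rows_b.append((f"{pid}_2_B", PLATFORM_PEA, pid, 2))
    cols = ["assay_id", "platform", "protein_id", "duplicate_rank"]
    return pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols)


def simulate_phenotypes(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Continuous outcome, survival time/event and covariates per sample.

    The continuous outcome is a sparse linear combination of latent
    protein levels plus covariate effects and Gaussian noise.  Event
    times follow an exponential proportional-hazards model whose linear
    predictor uses ``survival_coefs``; censoring is an independent
    exponential calibrated to ``censoring_rate``.
    """
    config = config or truth.config
    rng = np.random.default_rng((config.seed, 3))
    n = len(truth.sample_ids)

    age = rng.normal(60.0, 10.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    group = rng.integers(0, 3, size=n)
    if config.confounded_covariates:
        # optional mode: covariates leak into the first latent block
        age = age + 3.0 * truth.latent.iloc[:, 0].to_numpy()

    xb = truth.latent.to_numpy() @ truth.phenotype_coefs.to_numpy()
    outcome = (
        xb
        + 0.02 * (age - 60.0)
        + 0.5 * sex
        + 0.3 * (group == 1)
        - 0.2 * (group == 2)
        + config.phenotype_noise_sd * rng.standard_normal(n)
    )

    eta = truth.latent.to_numpy() @ truth.survival_coefs.to_numpy()
    eta = eta + 0.02 * (age - 60.0) + 0.3 * sex
    hazard = config.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        c = config.censoring_rate
        mu = c / (1.0 - c) * hazard.mean()
        censor_time = rng.exponential(1.0 / mu, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    return pd.DataFrame(
        {
            "outcome": outcome,
            "age": age,
            "sex": sex,
            "group": group.astype(int),
            "time": time,
            "event": event,
        },
        index=pd.Index(truth.sample_ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(
    truth: SimTruth,
    matrices: dict[str, ExpressionMatrix],
    phenotypes: pd.DataFrame,
    dir_path,
    na_token: str = DEFAULT_NA_TOKEN,
) -> dict[str, Path]:
    """Write matrices, mapping, phenotypes and a truth sidecar to disk.

    Everything round-trips through :func:`protbridge.harmonize.read_matrix`
    losslessly (up to float text formatting).
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, mat in matrices.items():
        path = dir_path / f"matrix_{key}.tsv"
        mat.to_tsv(path, na_token=na_token)
        paths[f"matrix_{key}"] = path

    map_a, map_b = assay_maps(truth)
    amap = pd.concat([map_a, map_b], ignore_index=True)
    paths["assay_map"] = dir_path / "assay_map.tsv"
    amap.to_csv(paths["assay_map"], sep="\t", index=False)

    paths["phenotypes"] = dir_path / "phenotypes.tsv"
    phenotypes.to_csv(paths["phenotypes"], sep="\t", na_rep=na_token)

    sidecar = {
        "class_labels": truth.class_labels.to_dict(),
        "subtype_labels": truth.subtype_labels.to_dict(),
        "off_target_source": {
            k: v for k, v in truth.off_target_source.items() if v
        },
        "phenotype_coefs": {
            k: v for k, v in truth.phenotype_coefs.items() if v != 0
        },
        "survival_coefs": {
            k: v for k, v in truth.survival_coefs.items() if v != 0
        },
        "seed": truth.config.seed,
    }
    paths["truth"] = dir_path / "truth.json"
    paths["truth"].write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return paths


def simulate_dataset(config: SimConfig) -> tuple[SimTruth, ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """One-call generation of truth, both platform matrices and phenotypes."""
    truth = simulate_latent(config)
    mat_a = measure_platform(truth, PLATFORM_APTAMER)
    mat_b = measure_platform(truth, PLATFORM_PEA)
    pheno = simulate_phenotypes(truth)
    return truth, mat_a, mat_b, pheno
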