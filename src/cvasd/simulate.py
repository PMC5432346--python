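"""Synthetic cohorts with planted treatment-sensitive genes.

Generates exactly the world the signature design assumes: standardized
expression for ``n_genes`` genes, a subset S of "sensitive" genes whose
(negative) treatment x expression interactions modulate the hazard, survival
times drawn from a Cox model with a parametric baseline via inverse-transform
sampling, independent censoring calibrated to a target censoring fraction,
and Bernoulli treatment assignment.

Ground truth is carried alongside the data: each patient's true generating
score exp(lambda + sum_{j in S} x_j (b_j + i_j)) — the nHR evaluated at the
generating coefficients with r = 1 — and the sensitivity label it implies,
so classifier-versus-truth comparisons are exact identities rather than
approximations.

Defaults describe a desk-scale cohort with a strong planted signal
(n = 300 patients, 100 genes, 10 sensitive genes with interaction -1.5, 30%
truly sensitive patients) and cohort-level nuisance parameters matching a
TCGA soft-tissue-sarcoma-like cohort: 30% treated, 60% censored, exponential
baseline with median survival 65.4 months.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigurationError, DataValidationError
from .preprocess import ExpressionMatrix, MergedDataset, SurvivalCohort

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate", "write_fixture"]

_HISTOLOGY_LEVELS = ("LMS", "DLS", "UPS", "other")
_HISTOLOGY_PROBS = (0.40, 0.23, 0.19, 0.18)


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic treatment-sensitivity cohort.

    ``i_true <= 0`` means higher expression of a sensitive gene confers a
    larger treatment benefit. ``sensitive_fraction_target``, when set,
    overrides ``r_threshold_true`` with the empirical quantile of the true
    scores so that the stated fraction of patients is truly sensitive.
    """

    n_patients: int = 300
    n_genes: int = 100
    n_sensitive_genes: int = 10
    lambda_true: float = 0.0
    b_true: float = 0.0
    i_true: float = -1.5
    sensitive_fraction_target: float | None = 0.3
    r_threshold_true: float = 0.5
    baseline: str = "exponential"        # or "weibull"
    baseline_rate: float = float(np.log(2) / 65.4)  # per month; median 65.4 mo
    weibull_shape: float = 1.2
    weibull_scale: float = 80.0
    censoring_rate: float = 0.6
    censoring_scheme: str = "exponential"  # or "administrative"
    treatment_prob: float = 0.3
    expression_marginal: str = "normal"   # or "lognormal" (RNAseq-like skew)
    include_covariates: bool = True
    covariate_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.treatment_prob < 1:
            raise ConfigurationError("treatment_prob must be in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        if self.n_sensitive_genes > self.n_genes:
            raise ConfigurationError("n_sensitive_genes cannot exceed n_genes")
        if self.baseline not in ("exponential", "weibull"):
            raise ConfigurationError(f"unknown baseline {self.baseline!r}")
        if self.censoring_scheme not in ("exponential", "administrative"):
            raise ConfigurationError(
                f"unknown censoring scheme {self.censoring_scheme!r}"
            )
        if self.expression_marginal not in ("normal", "lognormal"):
            raise ConfigurationError(
                f"unknown expression marginal {self.expression_marginal!r}"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))


@dataclass
class SyntheticCohort:
    """A simulated merged dataset plus per-patient and per-gene ground truth."""

    data: MergedDataset
    truth: pd.DataFrame          # patient_id, true_score, sensitive_true
    sensitive_genes: list        # gene ids in S
    r_threshold_true: float
    config: SimulationConfig

    @property
    def cohort(self) -> SurvivalCohort:
        return self.data.cohort

    @property
    def expression(self) -> ExpressionMatrix:
        return self.data.expression


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def simulate(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort from the configured generating model."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, config.n_genes
    Z = rng.standard_normal((n, p))
    if config.expression_marginal == "lognormal":
        Z = np.exp(0.8 * Z)
    X = _standardize_columns(Z)
    gene_ids = [f"G{j:04d}" for j in range(p)]
    patient_ids = [f"P{i:04d}" for i in range(n)]
    sens_idx = np.arange(config.n_sensitive_genes)
    sensitive_genes = [gene_ids[j] for j in sens_idx]

    r = (rng.random(n) < config.treatment_prob).astype(int)
    b = np.full(config.n_sensitive_genes, config.b_true, dtype=float)
    i = np.full(config.n_sensitive_genes, config.i_true, dtype=float)
    Xs = X[:, sens_idx]
    lp = r * config.lambda_true + Xs @ b + r * (Xs @ i)

    # inverse-transform event times: H0(T) = E / exp(lp), E ~ Exp(1)
    E = rng.exponential(size=n)
    if config.baseline == "exponential":
        T = E / (config.baseline_rate * np.exp(lp))
    else:
        T = config.weibull_scale * (E / np.exp(lp)) ** (1.0 / config.weibull_shape)

    if config.censoring_rate == 0:
        time, event = T, np.ones(n, dtype=int)
    elif config.censoring_scheme == "administrative":
        tau = float(np.quantile(T, 1.0 - config.censoring_rate))
        if tau <= 0:
            raise DataValidationError(
                "administrative censoring target unattainable: cutoff <= 0"
            )
        time = np.minimum(T, tau)
        event = (T <= tau).astype(int)
    else:
        # P(C < T_i | T_i) = 1 - exp(-c T_i); solve mean over the cohort
        def frac(c):
            return float(np.mean(1.0 - np.exp(-c * T))) - config.censoring_rate

        hi = 1.0
        while frac(hi) < 0 and hi < 1e12:
            hi *= 10.0
        lo = 1e-12
        if frac(lo) > 0 or frac(hi) < 0:
            raise DataValidationError(
                "censoring target unattainable; achievable range is "
                f"({frac(lo) + config.censoring_rate:.3f}, "
                f"{frac(hi) + config.censoring_rate:.3f})"
            )
        c = optimize.brentq(frac, lo, hi)
        C = rng.exponential(scale=1.0 / c, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    time = np.maximum(time, 1e-9)

    # ground truth: nHR at the generating coefficients, r = 1
    true_score = np.exp(config.lambda_true + Xs @ (b + i))
    if config.sensitive_fraction_target is not None:
        thr = float(np.quantile(true_score, config.sensitive_fraction_target))
    else:
        thr = config.r_threshold_true
    sensitive_true = true_score < thr

    clin = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "time": time,
            "event": event,
            "treatment": r,
        }
    )
    covariates = []
    if config.include_covariates:
        clin["age"] = np.clip(np.round(rng.normal(61, 12, size=n)), 20, 90)
        clin["gender"] = rng.choice(["female", "male"], size=n, p=[0.55, 0.45])
        clin["chemotherapy"] = rng.choice([0, 1], size=n, p=[0.77, 0.23])
        clin["histology"] = rng.choice(_HISTOLOGY_LEVELS, size=n, p=_HISTOLOGY_PROBS)
        covariates = ["age", "gender", "chemotherapy", "histology"]
        if config.covariate_missing_rate > 0:
            for col in covariates:
                mask = rng.random(n) < config.covariate_missing_rate
                clin.loc[mask, col] = np.nan

    cohort = SurvivalCohort(df=clin, covariates=covariates,
                            provenance={"source": "simulate", "seed": config.seed})
    expr = ExpressionMatrix(df=pd.DataFrame(X, index=patient_ids, columns=gene_ids))
    data = MergedDataset(cohort=cohort, expression=expr,
                         provenance={"source": "simulate", "seed": config.seed})
    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "true_score": true_score,
            "sensitive_true": sensitive_true.astype(int),
        }
    )
    return SyntheticCohort(
        data=data,
        truth=truth,
        sensitive_genes=sensitive_genes,
        r_threshold_true=thr,
        config=config,
    )


def write_fixture(cohort: SyntheticCohort, out_dir) -> dict:
    """Write a fixture directory consumable by the preprocessing pipeline.

    ``expression.tsv`` is written genes x patients in *raw* (non-negative,
    per-gene affine-rescaled) units so it passes the expression filters and
    round-trips: standardizing the written values recovers the simulated
    standardized matrix exactly (standardization is affine-invariant).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clin_path = out / "clinical.tsv"
    expr_path = out / "expression.tsv"
    truth_path = out / "truth.tsv"
    cohort.cohort.df.to_csv(clin_path, sep="\t", index=False)

    X = cohort.expression.values  # patients x genes, standardized
    lo = X.min(axis=0)
    rng_ = np.ptp(X, axis=0)
    raw = (X - lo) * (15.0 / rng_) + 0.01   # min 0.01, max 15.01 > filter cutoff
    raw_df = pd.DataFrame(
        raw.T, index=cohort.expression.gene_ids, columns=cohort.expression.patient_ids
    )
    raw_df.index.name = "gene_id"
    raw_df.to_csv(expr_path, sep="\t")

    truth = cohort.truth.copy()
    truth.to_csv(truth_path, sep="\t", index=False)
    (out / "config.json").write_text(cohort.config.to_json() + "\n")
    (out / "truth_meta.json").write_text(
        json.dumps(
            {
                "sensitive_genes": cohort.sensitive_genes,
                "r_threshold_true": cohort.r_threshold_true,
            },
            indent=2,
        )
        + "\n"
    )
    return {
        "clinical": str(clin_path),
        "expression": str(expr_path),
        "truth": str(truth_path),
        "config": str(out / "config.json"),
    }
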