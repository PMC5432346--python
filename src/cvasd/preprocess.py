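"""Reading, filtering, standardization and merging of clinical + expression inputs.

The pipeline mirrors the standard preprocessing of a TCGA-style cohort:

1. read the clinical table, dropping patients with missing treatment
   (radiotherapy) information;
2. filter the raw genes x patients expression matrix — genes whose maximum
   normalized expression is at or below a cutoff (default 10, i.e. genes
   showing almost no expression) are removed first, then genes with more
   than 75% exactly-zero values among the survivors;
3. standardize each remaining gene to mean 0 / sample SD 1 (denominator
   n - 1) across patients and transpose to patients x genes;
4. merge with the clinical table on the patient intersection.

Every removal is counted in a provenance record so the filter arithmetic can
be audited: genes_in = genes_out + removed_by_max_rule + removed_by_zero_rule_only.

Standardization is computed once on the full merged cohort, before any
cross-validation split; the resulting (mild) train/test information leakage
is a documented property of the design, not corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError

__all__ = [
    "ExpressionMatrix",
    "MergedDataset",
    "RawExpressionMatrix",
    "SurvivalCohort",
    "filter_genes",
    "impute_covariates",
    "merge",
    "read_clinical",
    "read_expression",
    "standardize",
]

DEFAULT_NA_VALUES = ["", "NA", "NaN", "nan", "null"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class RawExpressionMatrix:
    """Genes x patients non-negative normalized expression."""

    df: pd.DataFrame  # index: gene ids, columns: patient ids

    def __post_init__(self):
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.df.columns.duplicated().any():
            dups = self.df.columns[self.df.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate patient ids: {dups[:5]}")
        vals = self.df.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise DataValidationError("expression values must be finite")
        if np.any(vals < 0):
            raise DataValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list:
        return list(self.df.index)

    @property
    def patient_ids(self) -> list:
        return list(self.df.columns)

    @property
    def n_genes(self) -> int:
        return self.df.shape[0]


@dataclass
class ExpressionMatrix:
    """Patients x genes standardized expression (mean 0, sample SD 1 per gene)."""

    df: pd.DataFrame  # index: patient ids, columns: gene ids

    @property
    def gene_ids(self) -> list:
        return list(self.df.columns)

    @property
    def patient_ids(self) -> list:
        return list(self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)


@dataclass
class SurvivalCohort:
    """Per-patient follow-up, event, binary treatment and named covariates."""

    df: pd.DataFrame  # columns: patient_id, time, event, treatment, covariates...
    covariates: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        req = {"patient_id", "time", "event", "treatment"}
        missing = req - set(self.df.columns)
        if missing:
            raise ConfigurationError(f"cohort missing required columns: {sorted(missing)}")
        if self.df["patient_id"].duplicated().any():
            raise DataValidationError("duplicate patient ids in cohort")
        if (self.df["time"] <= 0).any() or self.df["time"].isna().any():
            raise DataValidationError("survival times must be positive")
        for col in ("event", "treatment"):
            bad = ~self.df[col].isin([0, 1])
            if bad.any():
                rows = self.df.index[bad].tolist()
                vals = self.df.loc[bad, col].unique().tolist()
                raise DataValidationError(
                    f"non-binary {col} values {vals} in rows {rows[:10]}"
                )

    @property
    def patient_ids(self) -> list:
        return list(self.df["patient_id"])

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def time(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=int)

    @property
    def treatment(self) -> np.ndarray:
        return self.df["treatment"].to_numpy(dtype=int)


@dataclass
class MergedDataset:
    """Analysis-ready cohort + expression pair with aligned patient order."""

    cohort: SurvivalCohort
    expression: ExpressionMatrix
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cohort.patient_ids != self.expression.patient_ids:
            raise DataValidationError(
                "cohort and expression patient ids differ or are ordered differently"
            )

    @property
    def n(self) -> int:
        return self.cohort.n


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_clinical(path, column_map: dict | None = None, sep: str = "\t",
                  na_values=None) -> SurvivalCohort:
    """Read a delimited clinical table into a :class:`SurvivalCohort`.

    ``column_map`` maps the roles {"id", "time", "event", "treatment"} (and
    optionally "covariates": a list) to column names in the file; defaults
    assume the roles are already the column names. Rows with missing
    treatment are dropped and counted; other missing covariate values are
    kept as NaN for downstream imputation.
    """
    column_map = dict(column_map or {})
    na_values = DEFAULT_NA_VALUES if na_values is None else na_values
    raw = pd.read_csv(path, sep=sep, na_values=na_values, keep_default_na=False,
                      dtype={column_map.get("id", "patient_id"): str})
    roles = {
        "id": column_map.get("id", "patient_id"),
        "time": column_map.get("time", "time"),
        "event": column_map.get("event", "event"),
        "treatment": column_map.get("treatment", "treatment"),
    }
    for role, col in roles.items():
        if col not in raw.columns:
            raise ConfigurationError(
                f"required column for {role!r} not found: {col!r} "
                f"(available: {list(raw.columns)})"
            )
    covs = column_map.get("covariates")
    if covs is None:
        covs = [c for c in raw.columns if c not in roles.values()]
    else:
        missing = [c for c in covs if c not in raw.columns]
        if missing:
            raise ConfigurationError(f"covariate columns not found: {missing}")
    df = raw[[roles["id"], roles["time"], roles["event"], roles["treatment"], *covs]]
    df = df.rename(
        columns={roles["id"]: "patient_id", roles["time"]: "time",
                 roles["event"]: "event", roles["treatment"]: "treatment"}
    )
    n0 = len(df)
    df = df[df["treatment"].notna()].reset_index(drop=True)
    dropped = n0 - len(df)
    for col in ("event", "treatment"):
        bad = df[col].notna() & ~df[col].isin([0, 1])
        if bad.any():
            raise DataValidationError(
                f"non-binary {col} values {df.loc[bad, col].unique().tolist()} "
                f"in rows {df.index[bad].tolist()[:10]}"
            )
        df[col] = df[col].astype(int)
    df["time"] = df["time"].astype(float)
    return SurvivalCohort(
        df=df,
        covariates=list(covs),
        provenance={"missing_treatment_dropped": dropped, "clinical_rows_in": n0},
    )


def read_expression(path, sep: str = "\t",
                    orientation: str = "genes_by_patients") -> RawExpressionMatrix:
    """Read a delimited expression matrix (first column = row identifiers).

    TCGA-style matrices ship genes x patients (the default); pass
    ``orientation="patients_by_genes"`` for the transposed layout.
    """
    if orientation not in ("genes_by_patients", "patients_by_genes"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "patients_by_genes":
        df = df.T
    return RawExpressionMatrix(df=df)


def filter_genes(raw: RawExpressionMatrix, max_expr_cutoff: float = 10.0,
                 zero_prop_cutoff: float = 0.75) -> RawExpressionMatrix:
    """Remove near-silent genes from a raw expression matrix.

    Rules, applied in order on the raw (pre-standardization) values:

    1. genes whose maximum expression is <= ``max_expr_cutoff`` (inclusive
       boundary: a gene peaking exactly at the cutoff still shows "almost no
       expression") are removed;
    2. among survivors, genes with a fraction of exactly-zero values
       strictly greater than ``zero_prop_cutoff`` are removed.

    Removal counts per rule land in the returned matrix's ``df.attrs`` under
    "provenance". Idempotent.
    """
    vals = raw.df.to_numpy(dtype=float)
    max_rule = vals.max(axis=1) <= max_expr_cutoff
    zero_prop = (vals == 0).mean(axis=1)
    zero_rule = zero_prop > zero_prop_cutoff
    keep = ~max_rule & ~zero_rule
    if not keep.any():
        raise DataValidationError(
            "all genes removed by expression filters; review max_expr_cutoff "
            f"({max_expr_cutoff}) and zero_prop_cutoff ({zero_prop_cutoff})"
        )
    out = RawExpressionMatrix(df=raw.df.loc[keep].copy())
    prev = raw.df.attrs.get("provenance", {})
    out.df.attrs["provenance"] = {
        "genes_in": prev.get("genes_in", raw.n_genes),
        "removed_by_max_rule": int(max_rule.sum()) + prev.get("removed_by_max_rule", 0),
        "removed_by_zero_rule_only": int((zero_rule & ~max_rule).sum())
        + prev.get("removed_by_zero_rule_only", 0),
        "genes_out": int(keep.sum()),
    }
    return out


def standardize(raw: RawExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene to mean 0 / sample SD 1 and transpose to patients x genes."""
    vals = raw.df.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        bad = [raw.gene_ids[j] for j in np.nonzero(zero_var)[0][:5]]
        raise DataValidationError(
            f"zero-variance gene(s) {bad}: remove them with filter_genes first"
        )
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    df = pd.DataFrame(z.T, index=raw.df.columns, columns=raw.df.index)
    out = ExpressionMatrix(df=df)
    if "provenance" in raw.df.attrs:
        out.df.attrs["provenance"] = dict(raw.df.attrs["provenance"])
    return out


def merge(cohort: SurvivalCohort, expr: ExpressionMatrix) -> MergedDataset:
    """Intersect patient sets and align ordering (cohort order wins)."""
    expr_ids = expr.patient_ids
    if len(set(expr_ids)) != len(expr_ids):
        raise DataValidationError("duplicate patient ids in expression matrix")
    common = [pid for pid in cohort.patient_ids if pid in set(expr_ids)]
    if len(common) < 2:
        raise DataValidationError(
            f"only {len(common)} patients in common between clinical and expression"
        )
    prov = {
        **cohort.provenance,
        **expr.df.attrs.get("provenance", {}),
        "patients_clinical_only": cohort.n - len(common),
        "patients_expression_only": len(expr_ids) - len(common),
        "patients_merged": len(common),
    }
    sub = cohort.df.set_index("patient_id").loc[common].reset_index()
    new_cohort = SurvivalCohort(df=sub, covariates=list(cohort.covariates))
    new_expr = ExpressionMatrix(df=expr.df.loc[common].copy())
    return MergedDataset(cohort=new_cohort, expression=new_expr, provenance=prov)


def impute_covariates(cohort: SurvivalCohort, strategy: str = "median_mode",
                      seed: int = 0) -> SurvivalCohort:
    """Fill (or drop) missing covariate values.

    ``median_mode``: numeric covariates get their median, categorical ones
    their mode (ties broken lexicographically) — a deterministic stand-in
    for chained-equation multiple imputation, adequate because covariates
    only feed the adjusted-Cox validation analyses, never the signature.
    ``drop_incomplete`` removes rows with any missing covariate. The ``seed``
    is accepted for interface stability; both strategies are deterministic.
    """
    if strategy not in ("median_mode", "drop_incomplete"):
        raise ConfigurationError(f"unknown imputation strategy {strategy!r}")
    for col in ("time", "event", "treatment"):
        if cohort.df[col].isna().any():
            raise DataValidationError(f"{col} must not contain missing values")
    df = cohort.df.copy()
    actions = {}
    if strategy == "drop_incomplete":
        if cohort.covariates:
            mask = df[cohort.covariates].notna().all(axis=1)
            actions["rows_dropped_incomplete"] = int((~mask).sum())
            df = df[mask].reset_index(drop=True)
    else:
        for col in cohort.covariates:
            s = df[col]
            if s.isna().all():
                raise DataValidationError(f"covariate {col!r} is entirely missing")
            n_missing = int(s.isna().sum())
            if n_missing == 0:
                continue
            if pd.api.types.is_numeric_dtype(s):
                fill = s.median()
            else:
                counts = s.dropna().value_counts()
                best = counts[counts == counts.max()].index
                fill = sorted(best.astype(str))[0]
            df[col] = s.fillna(fill)
            actions[f"imputed_{col}"] = n_missing
    return SurvivalCohort(
        df=df,
        covariates=list(cohort.covariates),
        provenance={**cohort.provenance, "imputation": strategy, **actions},
    )
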