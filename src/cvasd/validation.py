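"""Downstream validation battery for cross-validated sensitivity calls.

Given per-patient sensitivity calls, the battery mirrors the standard
post-hoc checks of a treatment-sensitivity signature:

- four-subgroup survival comparison (sensitive/nonsensitive x
  treated/untreated) with Kaplan-Meier curves and the four pairwise
  log-rank contrasts;
- covariate-adjusted Cox models of the treatment effect within each
  sensitivity stratum and of the sensitivity effect within each treatment
  arm (Wald inference);
- the same four contrasts repeated within levels of a categorical stratum
  (e.g. histologic type), with small levels merged;
- Fisher exact tests of a binary outcome (new tumor event, progressive
  disease) across the same contrasts;
- concordance between a two-group hierarchical clustering of the signature
  genes' expression and the sensitivity calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import CollinearityError, DataValidationError
from .preprocess import SurvivalCohort
from .survival import (
    CoxFit,
    KMCurve,
    LogRankResult,
    fisher_exact_2x2,
    fit_cox,
    km_curve,
    logrank,
)

__all__ = [
    "AdjustedEffect",
    "ConcordanceResult",
    "FourSubgroupResult",
    "adjusted_cox",
    "cluster_concordance",
    "four_subgroup_analysis",
    "outcome_rate_tests",
    "strata_analysis",
]

SUBGROUPS = ("RS+RT", "RS-RT", "NRS+RT", "NRS-RT")
CONTRASTS = (
    "RS: RT vs no-RT",
    "NRS: RT vs no-RT",
    "RT: RS vs NRS",
    "no-RT: RS vs NRS",
)


def _sensitive_vector(cohort: SurvivalCohort, calls) -> np.ndarray:
    """Align a calls table (or boolean vector) to the cohort's patient order."""
    if isinstance(calls, pd.DataFrame):
        s = calls.set_index("patient_id")["sensitive"]
        missing = [p for p in cohort.patient_ids if p not in s.index]
        if missing:
            raise DataValidationError(
                f"calls missing for patients: {missing[:5]}"
            )
        return s.loc[cohort.patient_ids].to_numpy().astype(bool)
    v = np.asarray(calls).astype(bool)
    if v.shape[0] != cohort.n:
        raise DataValidationError("calls vector length must match cohort size")
    return v


def subgroup_labels(cohort: SurvivalCohort, calls) -> np.ndarray:
    sens = _sensitive_vector(cohort, calls)
    rt = cohort.treatment.astype(bool)
    out = np.empty(cohort.n, dtype=object)
    out[sens & rt] = "RS+RT"
    out[sens & ~rt] = "RS-RT"
    out[~sens & rt] = "NRS+RT"
    out[~sens & ~rt] = "NRS-RT"
    return out


@dataclass
class FourSubgroupResult:
    """KM curves and the four pairwise log-rank contrasts of the 2x2 subgroups."""

    labels: np.ndarray
    sizes: dict
    km: dict                      # subgroup -> KMCurve (missing if empty)
    contrasts: dict               # contrast name -> LogRankResult or None

    def summary(self) -> str:
        lines = ["Four-subgroup survival analysis", "-" * 40]
        lines.append(
            "  ".join(f"{k}: n={v}" for k, v in self.sizes.items())
        )
        for name in CONTRASTS:
            t = self.contrasts.get(name)
            if t is None:
                lines.append(f"{name}: undefined")
            else:
                lines.append(
                    f"{name}: chi2={t.statistic:.4f} p={t.p:.4g}"
                )
        return "\n".join(lines)


def _safe_logrank(time, event, group):
    try:
        codes = pd.factorize(np.asarray(group))[0]
        if len(np.unique(codes)) < 2:
            return None
        return logrank(time, event, group)
    except DataValidationError:
        return None


def four_subgroup_analysis(cohort: SurvivalCohort, calls) -> FourSubgroupResult:
    """Survival comparison across sensitive/nonsensitive x treated/untreated.

    The four contrasts: treatment effect within the sensitive group, within
    the nonsensitive group, and the sensitivity effect within each treatment
    arm. Empty subgroups render the affected contrast undefined (None) with
    a warning rather than raising.
    """
    labels = subgroup_labels(cohort, calls)
    sizes = {g: int((labels == g).sum()) for g in SUBGROUPS}
    km = {}
    for g in SUBGROUPS:
        mask = labels == g
        if mask.any():
            km[g] = km_curve(cohort.time[mask], cohort.event[mask])
    sens = _sensitive_vector(cohort, calls)
    rt = cohort.treatment.astype(bool)
    t, e = cohort.time, cohort.event
    scopes = {
        "RS: RT vs no-RT": (sens, rt),
        "NRS: RT vs no-RT": (~sens, rt),
        "RT: RS vs NRS": (rt, sens),
        "no-RT: RS vs NRS": (~rt, sens),
    }
    contrasts = {}
    for name, (scope, grouping) in scopes.items():
        res = _safe_logrank(t[scope], e[scope], grouping[scope]) if scope.any() else None
        if res is None:
            warnings.warn(f"contrast {name!r} undefined (empty group or no events)",
                          UserWarning, stacklevel=2)
        contrasts[name] = res
    return FourSubgroupResult(labels=labels, sizes=sizes, km=km, contrasts=contrasts)


@dataclass
class AdjustedEffect:
    """One covariate-adjusted Cox contrast (hazard ratio with Wald inference)."""

    contrast: str
    hr: float
    ci95: tuple
    wald_p: float
    covariates: list
    converged: bool
    fit: CoxFit | None = None


def _design_with_covariates(df: pd.DataFrame, contrast_col: str,
                            covariates: list) -> pd.DataFrame:
    parts = [df[[contrast_col]].astype(float)]
    for cov in covariates:
        s = df[cov]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).to_frame())
        else:
            parts.append(pd.get_dummies(s, prefix=cov, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def _prune_design(design: pd.DataFrame, contrast_col: str) -> pd.DataFrame:
    """Drop aliased covariate columns, R-style, keeping the contrast.

    Constant columns (a category absent from the subgroup) and columns
    linearly dependent on the already-kept ones are dropped with a warning.
    A covariate collinear with the contrast itself is a caller error and
    raises, since the adjusted contrast would be meaningless.
    """
    X = design.to_numpy(dtype=float)
    cols = list(design.columns)
    c = X[:, 0] - X[:, 0].mean()
    kept = [0]
    dropped = []
    for j in range(1, X.shape[1]):
        v = X[:, j]
        if np.ptp(v) == 0:
            dropped.append(cols[j])
            continue
        vc = v - v.mean()
        if np.ptp(X[:, 0]) > 0:
            cos = abs(vc @ c) / (np.linalg.norm(vc) * np.linalg.norm(c))
            if cos > 1 - 1e-10:
                raise CollinearityError(
                    f"covariate column {cols[j]!r} is collinear with the "
                    f"contrast {contrast_col!r}"
                )
        centered = X[:, kept + [j]]
        centered = centered - centered.mean(axis=0)
        if np.linalg.matrix_rank(centered) > len(kept):
            kept.append(j)
        else:
            dropped.append(cols[j])
    if dropped:
        warnings.warn(
            f"dropping aliased/constant covariate column(s) {dropped} from "
            f"the {contrast_col!r} panel",
            UserWarning,
            stacklevel=3,
        )
    return design.iloc[:, kept]


def adjusted_cox(cohort: SurvivalCohort, calls, covariates: list | None = None,
                 ties: str = "efron") -> list[AdjustedEffect]:
    """Adjusted treatment/sensitivity hazard ratios for the four panels.

    Within the sensitive and nonsensitive strata the contrast is treatment;
    within the treated and untreated arms it is the sensitivity call. Each
    model adjusts for the supplied covariates (categoricals dummy-coded,
    first level as reference). Non-converged fits are flagged, never
    dropped silently; an empty covariate list reduces exactly to the
    unadjusted fit.
    """
    covariates = list(covariates or [])
    for cov in covariates:
        if cov not in cohort.df.columns:
            raise DataValidationError(f"covariate {cov!r} not in cohort")
        if cohort.df[cov].isna().any():
            raise DataValidationError(
                f"covariate {cov!r} has missing values; impute first"
            )
    sens = _sensitive_vector(cohort, calls)
    df = cohort.df.copy()
    df["_sensitive"] = sens.astype(int)
    panels = [
        ("RT vs no-RT | RS", sens, "treatment"),
        ("RT vs no-RT | NRS", ~sens, "treatment"),
        ("RS vs NRS | RT", cohort.treatment == 1, "_sensitive"),
        ("RS vs NRS | no-RT", cohort.treatment == 0, "_sensitive"),
    ]
    out = []
    for name, scope, contrast_col in panels:
        sub = df.loc[scope].reset_index(drop=True)
        if len(sub) == 0 or sub["event"].sum() == 0 or sub[contrast_col].nunique() < 2:
            warnings.warn(f"panel {name!r} undefined", UserWarning, stacklevel=2)
            out.append(AdjustedEffect(name, np.nan, (np.nan, np.nan), np.nan,
                                      covariates, False))
            continue
        design = _prune_design(
            _design_with_covariates(sub, contrast_col, covariates), contrast_col
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cox(sub["time"], sub["event"], design, ties=ties)
        except CollinearityError:
            warnings.warn(
                f"panel {name!r}: residual collinearity, effect flagged",
                UserWarning, stacklevel=2,
            )
            out.append(AdjustedEffect(name, np.nan, (np.nan, np.nan), np.nan,
                                      covariates, False))
            continue
        ci = fit.hr_ci[0]
        out.append(
            AdjustedEffect(
                contrast=name,
                hr=float(fit.hr[0]),
                ci95=(float(ci[0]), float(ci[1])),
                wald_p=float(fit.wald_p[0]),
                covariates=covariates,
                converged=bool(fit.converged and not fit.flagged),
                fit=fit,
            )
        )
    return out


def strata_analysis(cohort: SurvivalCohort, calls, stratum: str,
                    min_size: int = 30) -> dict:
    """Repeat the four-subgroup analysis within each level of a stratum.

    Levels with fewer than ``min_size`` patients are merged into "other"
    (small histologic types behave alike and individually lack events).
    """
    if stratum not in cohort.df.columns:
        raise DataValidationError(f"stratum column {stratum!r} not in cohort")
    s = cohort.df[stratum].astype(str)
    counts = s.value_counts()
    small = set(counts.index[counts < min_size])
    merged = s.where(~s.isin(small), "other")
    out = {}
    for level in sorted(merged.unique()):
        mask = (merged == level).to_numpy()
        sub_cohort = SurvivalCohort(
            df=cohort.df.loc[mask].reset_index(drop=True),
            covariates=list(cohort.covariates),
        )
        sens = _sensitive_vector(cohort, calls)[mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            out[level] = four_subgroup_analysis(sub_cohort, sens)
    return out


def outcome_rate_tests(cohort: SurvivalCohort, calls, outcome) -> dict:
    """Fisher exact tests of a binary outcome across the four contrasts.

    ``outcome`` is a per-patient 0/1 vector (or cohort column name); missing
    values are excluded pairwise. Returns contrast -> (2x2 table, p), with
    p None when a margin is zero.
    """
    if isinstance(outcome, str):
        outcome = cohort.df[outcome]
    y = pd.Series(np.asarray(outcome, dtype=float), dtype=float)
    if y.shape[0] != cohort.n:
        raise DataValidationError("outcome length must match cohort size")
    valid = y.notna().to_numpy()
    if not np.all(np.isin(y[valid], (0.0, 1.0))):
        raise DataValidationError("outcome must be binary (0/1) where observed")
    sens = _sensitive_vector(cohort, calls)
    rt = cohort.treatment.astype(bool)
    yv = y.to_numpy()
    scopes = {
        "RS: RT vs no-RT": (sens, rt),
        "NRS: RT vs no-RT": (~sens, rt),
        "RT: RS vs NRS": (rt, sens),
        "no-RT: RS vs NRS": (~rt, sens),
    }
    out = {}
    for name, (scope, grouping) in scopes.items():
        use = scope & valid
        g = grouping[use]
        o = yv[use].astype(int)
        table = np.array(
            [
                [int(((g == 1) & (o == 1)).sum()), int(((g == 1) & (o == 0)).sum())],
                [int(((g == 0) & (o == 1)).sum()), int(((g == 0) & (o == 0)).sum())],
            ]
        )
        try:
            p = fisher_exact_2x2(table)
        except DataValidationError:
            warnings.warn(f"contrast {name!r}: zero-margin table, p undefined",
                          UserWarning, stacklevel=2)
            p = None
        out[name] = (table, p)
    return out


@dataclass
class ConcordanceResult:
    """Agreement between a 2-group clustering and the sensitivity calls."""

    cluster_labels: np.ndarray
    concordance: float
    linkage: str
    metric: str


def cluster_concordance(expression, calls, linkage_method: str = "complete",
                        metric: str = "euclidean") -> ConcordanceResult:
    """Two-group hierarchical clustering of signature-gene expression vs calls.

    Patients are clustered on the signature genes (default Euclidean
    distance, complete linkage — the common expression-heatmap setting), the
    dendrogram cut at two groups, and concordance taken as the best
    label-assignment agreement with the sensitivity calls; it is therefore
    invariant to swapping the cluster labels and >= 0.5 by construction for
    balanced problems.
    """
    X = expression.to_numpy(dtype=float) if isinstance(expression, pd.DataFrame) \
        else np.asarray(expression, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise DataValidationError("need >= 2 patients and >= 1 signature gene")
    calls_v = np.asarray(calls).astype(bool)
    if calls_v.shape[0] != X.shape[0]:
        raise DataValidationError("calls length must match patient count")
    d = pdist(X, metric=metric)
    if np.all(d == 0):
        raise DataValidationError(
            "all patients have identical expression: clustering degenerate"
        )
    Z = hierarchy.linkage(d, method=linkage_method)
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    agree = float(np.mean((labels == 1) == calls_v))
    return ConcordanceResult(
        cluster_labels=labels,
        concordance=max(agree, 1.0 - agree),
        linkage=linkage_method,
        metric=metric,
    )


def plot_four_subgroups(result: FourSubgroupResult, path=None):
    """KM curves for the four subgroups with their 95% bands (one panel)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colors = {"RS+RT": "C0", "RS-RT": "C1", "NRS+RT": "C2", "NRS-RT": "C3"}
    for name, curve in result.km.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.surv])
        ax.step(t, s, where="post", label=name, color=colors.get(name))
        ax.fill_between(
            np.concatenate([[0.0], curve.times]),
            np.concatenate([[1.0], curve.lower]),
            np.concatenate([[1.0], curve.upper]),
            step="post", alpha=0.15, color=colors.get(name),
        )
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
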