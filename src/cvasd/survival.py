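"""Survival-analysis primitives.

Self-contained, numpy-vectorized implementations of the Cox proportional
hazards model (Efron or Breslow tie handling, Newton-Raphson with
step-halving, Wald inference), the Kaplan-Meier product-limit estimator with
Greenwood log-log confidence bands, the unweighted k-sample log-rank test
with exposed observed/expected tables, and a validated two-sided Fisher
exact test for 2x2 tables.

The Cox engine is written directly against the partial likelihood because
the cross-validated signature design fits tens of thousands of small
three-column models per run; a :class:`CoxWorkspace` caches the sort order
and risk-set structure of a (time, event) pair so only the design changes
between per-gene fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearityError,
    ConvergenceWarning,
    DataValidationError,
    MonotoneLikelihoodWarning,
)

__all__ = [
    "CoxFit",
    "CoxWorkspace",
    "GeneInteractionFit",
    "KMCurve",
    "LogRankResult",
    "fisher_exact_2x2",
    "fit_cox",
    "fit_single_gene_interaction",
    "km_curve",
    "logrank",
]

# coefficients beyond this magnitude on standardized covariates mean the
# partial likelihood is monotone (no finite maximizer)
_DIVERGENCE_BOUND = 30.0
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Results of a Cox proportional-hazards fit.

    Attributes
    ----------
    names : list of str
        Covariate names, in design order.
    coef : ndarray
        Log-hazard-ratio estimates.
    se : ndarray
        Standard errors from the inverse observed information.
    vcov : ndarray
        Covariance matrix of the estimates.
    loglik : float
        Maximized log partial likelihood.
    converged : bool
        Newton iteration converged (coefficient change below tolerance).
    flagged : bool
        Degenerate fit (zero-variance column, monotone likelihood, singular
        information); estimates should not be trusted and Wald p-values are 1.
    """

    names: list
    coef: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n: int
    n_events: int
    ties: str
    flagged: bool = False
    note: str = ""

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coef, index=self.names, name="coef")

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return np.where(np.isfinite(z), z, 0.0)

    @property
    def wald_p(self) -> np.ndarray:
        if self.flagged:
            return np.ones_like(self.coef)
        p = 2.0 * stats.norm.sf(np.abs(self.wald_z))
        return np.clip(p, _P_FLOOR, 1.0)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def hr_ci(self) -> np.ndarray:
        """95% confidence interval for the hazard ratios, shape (p, 2)."""
        z = stats.norm.ppf(0.975)
        with np.errstate(over="ignore"):
            lo = np.exp(self.coef - z * self.se)
            hi = np.exp(self.coef + z * self.se)
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.hr_ci
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se(coef)": self.se,
                "HR": self.hr,
                "HR 95% lower": ci[:, 0],
                "HR 95% upper": ci[:, 1],
                "z": self.wald_z,
                "p": self.wald_p,
            },
            index=self.names,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        status = "converged" if self.converged else "NOT converged"
        return (
            f"<CoxFit n={self.n} events={self.n_events} ties={self.ties} "
            f"{status}{' FLAGGED' if self.flagged else ''} "
            f"loglik={self.loglik:.4f}>"
        )


class CoxWorkspace:
    """Risk-set structure of a (time, event) pair, reusable across designs.

    Sorting, risk-set start indices and tied-event groups depend only on the
    follow-up data, so per-gene interaction fits on a fixed training cohort
    share one workspace.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or event.shape != time.shape:
            raise DataValidationError("time and event must be 1-d and equal length")
        if np.any(~np.isfinite(time)) or np.any(time <= 0):
            raise DataValidationError("survival times must be positive and finite")
        ev = event.astype(float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise DataValidationError("event indicator must be 0/1")
        order = np.argsort(time, kind="stable")
        self.order = order
        self.time = time[order]
        self.event = ev[order].astype(bool)
        self.n = time.shape[0]
        self.n_events = int(self.event.sum())
        if self.n_events == 0:
            raise DataValidationError("no events: Cox model undefined")
        # risk set of a subject = all subjects with time >= theirs; with an
        # ascending stable sort this is the suffix starting at the first
        # occurrence of their time
        self.risk_start = np.searchsorted(self.time, self.time, side="left")
        self.event_idx = np.nonzero(self.event)[0]
        # tied death groups (>=2 deaths at one time) need the Efron correction
        et = self.time[self.event_idx]
        self.tied_groups = []
        if et.size:
            uniq, inv, counts = np.unique(et, return_inverse=True, return_counts=True)
            for k in np.nonzero(counts > 1)[0]:
                idx = self.event_idx[inv == k]
                self.tied_groups.append((idx, self.risk_start[idx[0]]))

    # -- partial likelihood, gradient, Hessian --------------------------------

    def _lgh(self, Xs: np.ndarray, beta: np.ndarray, ties: str):
        eta = Xs @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        wx = w[:, None] * Xs
        wxx = wx[:, :, None] * Xs[:, None, :]
        rw = np.cumsum(w[::-1])[::-1]
        rwx = np.cumsum(wx[::-1], axis=0)[::-1]
        rwxx = np.cumsum(wxx[::-1], axis=0)[::-1]
        ei = self.event_idx
        rs = self.risk_start[ei]
        W = rw[rs]
        S1 = rwx[rs]
        S2 = rwxx[rs]
        # Breslow: every death at a tied time sees the full risk-set sums
        ll = float(np.sum(eta[ei] - shift - np.log(W)))
        xbar = S1 / W[:, None]
        grad = (Xs[ei] - xbar).sum(axis=0)
        hess = -(S2 / W[:, None, None]).sum(axis=0) + np.einsum("ij,ik->jk", xbar, xbar)
        if ties == "efron" and self.tied_groups:
            for idx, s in self.tied_groups:
                d = idx.shape[0]
                Wg, S1g, S2g = rw[s], rwx[s], rwxx[s]
                V = w[idx].sum()
                Vx = wx[idx].sum(axis=0)
                Vxx = wxx[idx].sum(axis=0)
                # back out the Breslow contribution of this group
                xb = S1g / Wg
                ll += d * np.log(Wg)
                grad += d * xb
                hess += d * (S2g / Wg - np.outer(xb, xb))
                # Efron: l-th tied death sees risk set depleted by l/d of the ties
                frac = np.arange(d) / d
                den = Wg - frac * V
                num = S1g[None, :] - frac[:, None] * Vx
                S2l = S2g[None, :, :] - frac[:, None, None] * Vxx
                ll -= float(np.log(den).sum())
                grad -= (num / den[:, None]).sum(axis=0)
                hess -= (S2l / den[:, None, None]).sum(axis=0) - np.einsum(
                    "lj,lk,l->jk", num, num, den**-2
                )
        return ll, grad, hess

    def fit(self, design, names=None, ties: str = "efron", max_iter: int = 50,
            tol: float = 1e-9) -> CoxFit:
        """Maximize the log partial likelihood for a design matrix.

        Degenerate (zero-variance) columns yield a flagged fit with zero
        coefficients and Wald p = 1. A rank-deficient design with
        non-degenerate columns raises :class:`CollinearityError`. A monotone
        likelihood is reported as a non-converged fit with a warning.
        """
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie convention {ties!r}")
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.n:
            raise DataValidationError("design rows must match time/event length")
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        names = list(names)
        p = X.shape[1]

        def _flagged(note: str) -> CoxFit:
            return CoxFit(
                names=names,
                coef=np.zeros(p),
                se=np.full(p, np.inf),
                vcov=np.full((p, p), np.nan),
                loglik=np.nan,
                converged=False,
                n=self.n,
                n_events=self.n_events,
                ties=ties,
                flagged=True,
                note=note,
            )

        if np.any(np.ptp(X, axis=0) == 0):
            bad = [names[j] for j in np.nonzero(np.ptp(X, axis=0) == 0)[0]]
            warnings.warn(
                f"degenerate (constant) covariate column(s) {bad}: flagged fit",
                ConvergenceWarning,
                stacklevel=2,
            )
            return _flagged(f"degenerate columns: {bad}")

        Xs = X[self.order]
        beta = np.zeros(p)
        ll, grad, hess = self._lgh(Xs, beta, ties)
        if np.linalg.cond(-hess) > 1e12:
            raise CollinearityError(
                "design columns are collinear to machine precision"
            )
        converged = False
        monotone = False
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                warnings.warn(
                    "singular information matrix during Newton iteration",
                    ConvergenceWarning,
                    stacklevel=2,
                )
                return _flagged("singular information matrix")
            # step-halving keeps the likelihood non-decreasing
            for _h in range(30):
                cand = beta + step
                ll_new, grad_new, hess_new = self._lgh(Xs, cand, ties)
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
            if np.max(np.abs(beta)) > _DIVERGENCE_BOUND:
                monotone = True
                break
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        if monotone:
            warnings.warn(
                "monotone partial likelihood: a covariate perfectly orders the "
                "events; no finite maximizer exists",
                MonotoneLikelihoodWarning,
                stacklevel=2,
            )
        elif not converged:
            warnings.warn(
                f"Cox fit did not converge in {max_iter} iterations",
                ConvergenceWarning,
                stacklevel=2,
            )
        try:
            vcov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(vcov), 0, np.inf))
        except np.linalg.LinAlgError:
            vcov = np.full((p, p), np.nan)
            se = np.full(p, np.inf)
        return CoxFit(
            names=names,
            coef=beta,
            se=se,
            vcov=vcov,
            loglik=ll,
            converged=converged,
            n=self.n,
            n_events=self.n_events,
            ties=ties,
            flagged=False,
            note="monotone likelihood" if monotone else "",
        )


def fit_cox(time, event, design, ties: str = "efron", max_iter: int = 50,
            tol: float = 1e-9) -> CoxFit:
    """Fit a Cox proportional-hazards model h(t|x) = h0(t) exp(x'beta).

    Parameters
    ----------
    time, event : array-like
        Positive follow-up times and 0/1 event indicators.
    design : DataFrame or 2-d array
        Covariate matrix; DataFrame column names label the coefficients.
    ties : {"efron", "breslow"}
        Tied-event-time convention. Efron is the default; both agree exactly
        when no event times are tied.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        names = None
        X = np.asarray(design, dtype=float)
    ws = CoxWorkspace(time, event)
    return ws.fit(X, names=names, ties=ties, max_iter=max_iter, tol=tol)


# ---------------------------------------------------------------------------
# single-gene treatment x expression interaction screen
# ---------------------------------------------------------------------------


@dataclass
class GeneInteractionFit:
    """One gene's screen fit: h(t) = h0(t) exp(r*lam + x*b + r*x*i).

    ``p_interaction`` is the two-sided Wald p-value for the interaction
    coefficient ``i_hat``; flagged (degenerate or non-converged) fits carry
    p_interaction = 1 so they rank last.
    """

    gene_id: str
    lambda_hat: float
    b_hat: float
    i_hat: float
    se_lambda: float
    se_b: float
    se_i: float
    p_interaction: float
    converged: bool

    @property
    def flagged(self) -> bool:
        return not self.converged


def fit_single_gene_interaction(time, event, treatment, x, gene_id: str = "gene",
                                ties: str = "efron",
                                workspace: CoxWorkspace | None = None,
                                ) -> GeneInteractionFit:
    """Screen one gene for a treatment-modifying effect on the hazard.

    Fits the three-column design (treatment r, expression x, interaction r*x)
    and returns the coefficients with the Wald p-value of the interaction.
    Degenerate designs (constant expression, interaction collinear with the
    main effects) and monotone likelihoods yield a flagged fit with
    ``p_interaction = 1`` rather than an exception.
    """
    r = np.asarray(treatment, dtype=float)
    xv = np.asarray(x, dtype=float)
    ev = np.asarray(event, dtype=float)
    if not (np.any(ev[r == 1] == 1) and np.any(ev[r == 0] == 1)):
        raise DataValidationError(
            "both treatment arms must contain at least one event"
        )
    if workspace is None:
        workspace = CoxWorkspace(time, event)

    def _flagged() -> GeneInteractionFit:
        return GeneInteractionFit(
            gene_id=gene_id, lambda_hat=0.0, b_hat=0.0, i_hat=0.0,
            se_lambda=np.inf, se_b=np.inf, se_i=np.inf,
            p_interaction=1.0, converged=False,
        )

    design = np.column_stack([r, xv, r * xv])
    names = ["treatment", gene_id, f"treatment:{gene_id}"]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = workspace.fit(design, names=names, ties=ties)
    except CollinearityError:
        warnings.warn(
            f"gene {gene_id}: degenerate interaction design, flagged (p=1)",
            ConvergenceWarning,
            stacklevel=2,
        )
        return _flagged()
    if fit.flagged or not fit.converged:
        warnings.warn(
            f"gene {gene_id}: degenerate or non-converged interaction fit, "
            "flagged (p=1)",
            ConvergenceWarning,
            stacklevel=2,
        )
        return _flagged()
    p = fit.wald_p
    return GeneInteractionFit(
        gene_id=gene_id,
        lambda_hat=float(fit.coef[0]),
        b_hat=float(fit.coef[1]),
        i_hat=float(fit.coef[2]),
        se_lambda=float(fit.se[0]),
        se_b=float(fit.se[1]),
        se_i=float(fit.se[2]),
        p_interaction=float(p[2]),
        converged=True,
    )


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------


@dataclass
class LogRankResult:
    """Unweighted k-sample log-rank test.

    ``observed`` and ``expected`` are per-group event counts summed over the
    pooled distinct event times; ``statistic`` is the chi-squared value on
    ``df = k - 1`` degrees of freedom.
    """

    statistic: float
    df: int
    p: float
    groups: list
    observed: np.ndarray
    expected: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"observed": self.observed, "expected": self.expected},
            index=self.groups,
        )


def logrank(time, event, group) -> LogRankResult:
    """Log-rank test of survival-curve equality across groups.

    Standard (unweighted) test: at each distinct pooled event time, each
    group's expected events are d * n_g / n; the statistic is the quadratic
    form of observed-minus-expected against the hypergeometric covariance.
    """
    time = np.asarray(time, dtype=float)
    ev = np.asarray(event, dtype=float)
    codes, uniques = pd.factorize(np.asarray(group))
    k = len(uniques)
    if k < 2:
        raise DataValidationError("log-rank test needs >= 2 nonempty groups")
    if ev.sum() == 0:
        raise DataValidationError("log-rank test undefined with zero events")
    et = np.unique(time[ev == 1])
    T = et.shape[0]
    n_at_risk = np.empty((T, k))
    observed_t = np.empty((T, k))
    for g in range(k):
        tg = np.sort(time[codes == g])
        n_at_risk[:, g] = tg.shape[0] - np.searchsorted(tg, et, side="left")
        teg = np.sort(time[(codes == g) & (ev == 1)])
        observed_t[:, g] = np.searchsorted(teg, et, side="right") - np.searchsorted(
            teg, et, side="left"
        )
    n_tot = n_at_risk.sum(axis=1)
    d_tot = observed_t.sum(axis=1)
    pi = n_at_risk / n_tot[:, None]
    expected_t = d_tot[:, None] * pi
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    Vfull = np.diag(np.einsum("t,tg->g", c, pi)) - np.einsum(
        "t,tg,th->gh", c, pi, pi
    )
    z = (observed_t - expected_t).sum(axis=0)
    sub = Vfull[: k - 1, : k - 1]
    zsub = z[: k - 1]
    try:
        stat = float(zsub @ np.linalg.solve(sub, zsub))
    except np.linalg.LinAlgError:
        stat = float(zsub @ np.linalg.pinv(sub) @ zsub)
    stat = max(stat, 0.0)
    p = float(np.clip(stats.chi2.sf(stat, k - 1), _P_FLOOR, 1.0))
    return LogRankResult(
        statistic=stat,
        df=k - 1,
        p=p,
        groups=list(uniques),
        observed=observed_t.sum(axis=0),
        expected=expected_t.sum(axis=0),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival estimate with a Greenwood log-log 95% band."""

    times: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    conf: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "surv": self.surv,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.surv[i - 1])


def km_curve(time, event, conf: float = 0.95) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    The confidence band uses the Greenwood variance on the log(-log S)
    scale, which keeps the band inside [0, 1]; at S = 0 or 1 the band
    collapses onto the estimate.
    """
    time = np.asarray(time, dtype=float)
    ev = np.asarray(event, dtype=float)
    if time.size == 0:
        raise DataValidationError("empty input")
    et = np.unique(time[ev == 1])
    ts = np.sort(time)
    tes = np.sort(time[ev == 1])
    at_risk = time.shape[0] - np.searchsorted(ts, et, side="left")
    d = np.searchsorted(tes, et, side="right") - np.searchsorted(tes, et, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    # Greenwood: Var[S] = S^2 * sum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf))
        z = stats.norm.ppf(0.5 + conf / 2.0)
        logs = np.log(surv, out=np.full_like(surv, -np.inf), where=surv > 0)
        se_ll = np.sqrt(gw) / np.abs(logs)
        lower = surv ** np.exp(z * se_ll)
        upper = surv ** np.exp(-z * se_ll)
    lower = np.where(np.isfinite(lower), lower, surv)
    upper = np.where(np.isfinite(upper), upper, surv)
    return KMCurve(
        times=et,
        surv=surv,
        at_risk=at_risk.astype(int),
        events=d.astype(int),
        lower=lower,
        upper=upper,
        conf=conf,
    )


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integer counts.

    Two-sided p sums hypergeometric probabilities no larger than that of the
    observed table (the standard convention). All four margins must be
    positive.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DataValidationError("table must be 2x2")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise DataValidationError("counts must be nonnegative integers")
    t = t.astype(np.int64)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DataValidationError("all margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
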