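"""Survival-analysis chain for RSD covariates.

The statistical pipeline applied to the per-subject regression slope
directionalities (RSDs):

1. univariate Cox proportional-hazards screening of each binary covariate
   (Newton-Raphson on the partial likelihood, Efron tie handling, Wald
   confidence intervals), keeping covariates with p < 0.1;
2. Farrar-Glauber multicollinearity diagnostics on the RSD design
   (determinant chi-square test, per-variable F tests, pairwise partial
   correlations with t tests);
3. adaptive-LASSO Cox selection on the screened covariates: adaptive
   weights w_j = 1/|beta_ridge_j|^gamma from a ridge-stabilised initial
   fit, an L1-penalised partial-likelihood path solved by proximal Newton
   with coordinate descent, and the penalty chosen by seeded K-fold
   cross-validated partial likelihood (Verweij-van Houwelingen);
4. unpenalised univariate Cox refits of the selected covariates (the
   reported HR/CI/p), and Kaplan-Meier curves (Greenwood variance,
   log-transformed 95% CI, median survival) stratified by each selected
   covariate.

The Cox engine is self-contained so that the same partial-likelihood
code backs both the unpenalised fits and the weighted-L1 path; tests
cross-check it against an independent implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ENDPOINTS = ("PFS", "OS")


class ConvergenceError(RuntimeError):
    """Monotone partial likelihood (complete separation) or failed Newton fit."""


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties)
# ---------------------------------------------------------------------------

def cox_loglik(beta, X, time, event):
    """Log partial likelihood, gradient and Hessian at ``beta`` (Efron ties).

    For each distinct event time with d tied events D and risk set R:

        l += sum_{i in D} eta_i - sum_{l=0}^{d-1} log(S_R - (l/d) S_D)

    with S_R, S_D the risk-set and tied-set sums of exp(eta). Gradient and
    Hessian use the corresponding Efron-weighted means. Returns
    (loglik, grad, hess) where hess is the Hessian of the log likelihood
    (negative semi-definite).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.size(time):
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n, p = X.shape

    order = np.argsort(time, kind="stable")
    t, d, Xs = time[order], event[order], X[order]
    eta = Xs @ beta
    shift = eta.max() if n else 0.0  # overflow guard; cancels in ratios
    w = np.exp(eta - shift)

    # reverse cumulative sums: index i -> sum over all j with t_j >= t_i
    S = np.cumsum(w[::-1])[::-1]
    wx = w[:, None] * Xs
    Sx = np.cumsum(wx[::-1], axis=0)[::-1]
    wxx = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    Sxx = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev_times = t[d]
    if ev_times.size == np.unique(ev_times).size:
        # no tied events: Efron reduces to Breslow; fully vectorised
        fi = np.searchsorted(t, ev_times, side="left")
        den = S[fi]
        mu = Sx[fi] / den[:, None]
        ll = float(eta[d].sum()) - ev_times.size * shift - float(np.log(den).sum())
        grad = Xs[d].sum(axis=0) - mu.sum(axis=0)
        hess = -(Sxx[fi] / den[:, None, None]
                 - mu[:, :, None] * mu[:, None, :]).sum(axis=0)
        return ll, grad, hess

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = d[i:j]
        if ev.any():
            idx = np.arange(i, j)[ev]
            dcount = idx.size
            wD = w[idx]
            SD = wD.sum()
            VD = wx[idx].sum(axis=0)
            QD = wxx[idx].sum(axis=0)
            ll += float(eta[idx].sum()) - dcount * shift
            grad += Xs[idx].sum(axis=0)
            fracs = np.arange(dcount) / dcount
            for f in fracs:
                den = S[i] - f * SD
                mu = (Sx[i] - f * VD) / den
                # log(true den) = log(den) + shift; the shift is already
                # subtracted from the eta sum above, so terms balance
                ll -= float(np.log(den))
                grad -= mu
                hess -= (Sxx[i] - f * QD) / den - np.outer(mu, mu)
        i = j
    return ll, grad, hess


def cox_fit(X, time, event, ridge: float = 0.0, init=None,
            max_iter: int = 100, tol: float = 1e-10, names=None):
    """Maximise the (optionally ridge-penalised) Cox partial likelihood.

    Newton-Raphson with step halving. Returns (beta, loglik, cov) where
    cov is the inverse observed information of the *penalised* objective.

    Raises
    ------
    ConvergenceError
        On monotone likelihood (coefficients diverging — complete
        separation) or failure to converge.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.size(time):
        X = X.T
    n, p = X.shape
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()

    def objective(b):
        ll, g, H = cox_loglik(b, X, time, event)
        if ridge > 0:
            ll -= 0.5 * ridge * float(b @ b)
            g = g - ridge * b
            H = H - ridge * np.eye(p)
        return ll, g, H

    ll, g, H = objective(beta)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol * max(1.0, abs(ll)):
            break
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step halving on the objective
        s = 1.0
        for _ in range(40):
            ll_new, g_new, H_new = objective(beta + s * step)
            if ll_new >= ll - 1e-12:
                break
            s *= 0.5
        beta = beta + s * step
        ll, g, H = ll_new, g_new, H_new
    else:
        raise ConvergenceError("Newton-Raphson did not converge")
    if np.max(np.abs(beta)) > 15:
        which = names[int(np.argmax(np.abs(beta)))] if names else \
            f"column {int(np.argmax(np.abs(beta)))}"
        raise ConvergenceError(
            f"monotone partial likelihood (complete separation) for {which}"
        )
    cov = np.linalg.inv(-H)
    return beta, ll, cov


@dataclass(frozen=True)
class CoxResult:
    """One covariate's proportional-hazards estimate."""

    name: str
    coef: float
    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    n_events: int
    ties: str = "efron"

    def as_dict(self) -> dict:
        return {
            "name": self.name, "coef": self.coef, "hr": self.hr,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "p_value": self.p_value, "n": self.n, "n_events": self.n_events,
            "ties": self.ties,
        }


def cox_univariate(covariate, time, event, name: str = "x") -> CoxResult:
    """Univariate Cox regression of a binary covariate.

    Wald statistics: CI = exp(beta +/- 1.96 se), p from the two-sided
    normal test of beta/se.

    Raises
    ------
    ValueError
        No events, or fewer than 2 subjects at a covariate level.
    ConvergenceError
        Complete separation, naming the covariate.
    """
    x = np.asarray(covariate, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if event.sum() < 1:
        raise ValueError(f"no events for covariate {name}")
    levels, counts = np.unique(x, return_counts=True)
    if levels.size >= 2 and counts.min() < 2:
        raise ValueError(
            f"covariate {name}: fewer than 2 subjects at level "
            f"{levels[int(np.argmin(counts))]:g}"
        )
    beta, _, cov = cox_fit(x[:, None], time, event, names=[name])
    se = float(np.sqrt(cov[0, 0]))
    b = float(beta[0])
    z = b / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(
        name=name, coef=b, hr=float(np.exp(b)),
        ci_lower=float(np.exp(b - 1.959963984540054 * se)),
        ci_upper=float(np.exp(b + 1.959963984540054 * se)),
        p_value=float(p), n=int(x.size), n_events=int(event.sum()),
    )


def screen_covariates(results, threshold: float = 0.1) -> list:
    """Names of covariates with Wald p strictly below ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return [r.name for r in results if r.p_value < threshold]


# ---------------------------------------------------------------------------
# Farrar-Glauber multicollinearity diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FarrarGlauberResult:
    """Determinant chi-square test, per-variable F tests and partial correlations."""

    names: tuple
    chi_square: float
    chi_square_df: int
    chi_square_p: float
    f_statistics: np.ndarray
    f_p_values: np.ndarray
    partial_corr: np.ndarray
    partial_corr_p: np.ndarray

    def partial_corr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.partial_corr, index=self.names, columns=self.names)

    def as_dict(self) -> dict:
        return {
            "names": list(self.names),
            "chi_square": self.chi_square,
            "chi_square_df": self.chi_square_df,
            "chi_square_p": self.chi_square_p,
            "f_statistics": dict(zip(self.names, self.f_statistics.tolist())),
            "f_p_values": dict(zip(self.names, self.f_p_values.tolist())),
            "partial_corr": self.partial_corr.tolist(),
            "partial_corr_p": self.partial_corr_p.tolist(),
        }


def farrar_glauber(X, names=None) -> FarrarGlauberResult:
    """Farrar-Glauber multicollinearity test on an n x p design.

    Overall statistic: chi2 = -[n - 1 - (2p + 5)/6] * ln det(R) on
    p(p-1)/2 degrees of freedom, where R is the sample correlation matrix.
    Per-variable F_i = (R^{-1}_ii - 1) * (n - p)/(p - 1) on (p-1, n-p) df.
    Partial correlations r_ij = -R^{-1}_ij / sqrt(R^{-1}_ii R^{-1}_jj),
    tested with t = r sqrt((n - p)/(1 - r^2)) on n - p df.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 covariates")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    names = tuple(names) if names is not None else tuple(f"x{i}" for i in range(p))

    sd = X.std(axis=0, ddof=1)
    constant = [names[i] for i in range(p) if sd[i] == 0]
    if constant:
        raise np.linalg.LinAlgError(
            f"singular correlation matrix; constant columns: {constant}"
        )
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or logdet < -700:
        # identify perfectly collinear columns via the QR rank structure
        rank = np.linalg.matrix_rank(R)
        raise np.linalg.LinAlgError(
            f"singular correlation matrix (rank {rank} < {p}); "
            f"columns {list(names)} are linearly dependent"
        )
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    chi2_p = float(stats.chi2.sf(chi2, df))

    Rinv = np.linalg.inv(R)
    diag = np.diag(Rinv)
    f_stats = (diag - 1.0) * (n - p) / (p - 1)
    f_p = stats.f.sf(f_stats, p - 1, n - p)

    denom = np.sqrt(np.outer(diag, diag))
    partial = -Rinv / denom
    np.fill_diagonal(partial, 1.0)
    partial = np.clip(partial, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = partial * np.sqrt((n - p) / (1.0 - partial ** 2))
    part_p = 2.0 * stats.t.sf(np.abs(tstat), n - p)
    np.fill_diagonal(part_p, 0.0)

    return FarrarGlauberResult(
        names=names, chi_square=float(chi2), chi_square_df=int(df),
        chi_square_p=chi2_p, f_statistics=np.asarray(f_stats),
        f_p_values=np.asarray(f_p), partial_corr=partial,
        partial_corr_p=np.asarray(part_p),
    )


# ---------------------------------------------------------------------------
# Adaptive LASSO Cox
# ---------------------------------------------------------------------------

def _soft(u, lam):
    return np.sign(u) * max(abs(u) - lam, 0.0)


def _lasso_cox_solve(X, time, event, lam, beta_init,
                     max_outer: int = 60, tol: float = 1e-9):
    """Proximal-Newton solver for min -l(beta) + lam * ||beta||_1.

    Each outer step builds the quadratic model of -l at the current point
    and minimises model + L1 by cyclic coordinate descent, then line
    searches on the true penalised objective.
    """
    n, p = X.shape
    beta = beta_init.copy()
    ll, g, H = cox_loglik(beta, X, time, event)
    A = -H  # positive semi-definite curvature
    A = A + 1e-10 * np.eye(p)
    obj = -ll + lam * np.abs(beta).sum()
    for _ in range(max_outer):
        b = beta.copy()
        for _ in range(200):
            max_delta = 0.0
            for j in range(p):
                # stationarity in coordinate j of the quadratic model:
                # -g_j + [A (b - beta)]_j + lam * sign(b_j) = 0
                c = -g[j] + A[j] @ (b - beta) - A[j, j] * (b[j] - beta[j])
                u = A[j, j] * beta[j] - c
                new = _soft(u, lam) / A[j, j]
                max_delta = max(max_delta, abs(new - b[j]))
                b[j] = new
            if max_delta < 0.1 * tol:
                break
        delta = b - beta
        if np.max(np.abs(delta)) < tol:
            break
        s = 1.0
        for _ in range(40):
            cand = beta + s * delta
            ll_c, g_c, H_c = cox_loglik(cand, X, time, event)
            obj_c = -ll_c + lam * np.abs(cand).sum()
            if obj_c <= obj + 1e-12:
                break
            s *= 0.5
        beta, ll, g, H, obj = cand, ll_c, g_c, H_c, obj_c
        A = -H + 1e-10 * np.eye(p)
    return beta, ll


@dataclass
class AlassoResult:
    """Adaptive-LASSO Cox selection outcome."""

    names: tuple
    selected: tuple
    coefficients: dict          # penalised coefficients at the chosen lambda
    weights: dict               # adaptive weights w_j
    lambda_grid: np.ndarray
    lambda_chosen: float
    cv_partial_loglik: np.ndarray
    refits: dict                # selected name -> unpenalised univariate CoxResult

    def as_dict(self) -> dict:
        return {
            "names": list(self.names),
            "selected": list(self.selected),
            "coefficients": self.coefficients,
            "weights": self.weights,
            "lambda_grid": self.lambda_grid.tolist(),
            "lambda_chosen": self.lambda_chosen,
            "cv_partial_loglik": self.cv_partial_loglik.tolist(),
            "refits": {k: v.as_dict() for k, v in self.refits.items()},
        }


def alasso_cox(X, time, event, names=None, gamma: float = 1.0,
               n_folds: int = 5, seed: int = 0, ridge_init: float = 0.1,
               n_lambda: int = 40, lambda_min_ratio: float = 1e-3) -> AlassoResult:
    """Adaptive-LASSO Cox variable selection.

    Adaptive weights w_j = 1/|beta_j|^gamma come from a ridge-stabilised
    initial Cox fit (the screened RSD covariates are collinear, so the
    plain MLE is a poor weight source). The weighted-L1 problem is solved
    on the rescaled design X_j/w_j over a log-spaced lambda grid with warm
    starts; lambda is chosen to maximise the seeded K-fold cross-validated
    partial likelihood cvl = sum_k [l(beta_{-k}) - l_{-k}(beta_{-k})].
    Ties in cvl go to the larger (sparser) lambda. Each selected covariate
    is reported via an unpenalised univariate Cox refit.

    An empty selection (everything shrunk to zero, or an all-zero design)
    returns a result with a warning rather than raising.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.size(time):
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n, p = X.shape
    if p == 0:
        raise ValueError("screened covariate set is empty")
    if n_folds < 3:
        raise ValueError("n_folds must be >= 3")
    names = tuple(names) if names is not None else tuple(f"x{i}" for i in range(p))

    empty = AlassoResult(
        names=names, selected=(), coefficients={m: 0.0 for m in names},
        weights={m: float("inf") for m in names},
        lambda_grid=np.array([]), lambda_chosen=float("nan"),
        cv_partial_loglik=np.array([]), refits={},
    )
    if not np.any(X.std(axis=0) > 0):
        warnings.warn("design has no varying columns; empty selection",
                      RuntimeWarning, stacklevel=2)
        return empty

    beta_init, _, _ = cox_fit(X, time, event, ridge=ridge_init, names=list(names))
    w = 1.0 / np.maximum(np.abs(beta_init), 1e-8) ** gamma
    Xw = X / w  # column rescaling turns the weighted L1 into a plain L1

    _, g0, _ = cox_loglik(np.zeros(p), Xw, time, event)
    lam_max = float(np.max(np.abs(g0)))
    if lam_max <= 0:
        warnings.warn("zero gradient at the null model; empty selection",
                      RuntimeWarning, stacklevel=2)
        return empty
    grid = lam_max * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)

    def path(Xd, td, ed):
        betas = np.zeros((n_lambda, p))
        b = np.zeros(p)
        for k, lam in enumerate(grid):
            b, _ = _lasso_cox_solve(Xd, td, ed, lam, b)
            betas[k] = b
        return betas

    # cross-validated partial likelihood (Verweij-van Houwelingen)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    cvl = np.zeros(n_lambda)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        if event[train].sum() == 0:
            continue
        betas_k = path(Xw[train], time[train], event[train])
        for k in range(n_lambda):
            l_full, _, _ = cox_loglik(betas_k[k], Xw, time, event)
            l_train, _, _ = cox_loglik(betas_k[k], Xw[train], time[train], event[train])
            cvl[k] += l_full - l_train

    best = int(np.argmax(cvl))
    ties_mask = cvl >= cvl[best] - 1e-12
    best = int(np.flatnonzero(ties_mask)[0])  # grid descends: first = sparsest
    lam_star = float(grid[best])

    betas_full = path(Xw, time, event)
    theta = betas_full[best]
    beta_hat = theta / w  # back to the original scale
    sel = tuple(names[j] for j in range(p) if abs(beta_hat[j]) > 1e-8)
    if not sel:
        warnings.warn("adaptive LASSO shrank every coefficient to zero",
                      RuntimeWarning, stacklevel=2)

    refits = {}
    for name in sel:
        j = names.index(name)
        refits[name] = cox_univariate(X[:, j], time, event, name=name)

    return AlassoResult(
        names=names, selected=sel,
        coefficients={names[j]: float(beta_hat[j]) for j in range(p)},
        weights={names[j]: float(w[j]) for j in range(p)},
        lambda_grid=grid, lambda_chosen=lam_star,
        cv_partial_loglik=cvl, refits=refits,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmGroup:
    """Product-limit estimate for one stratum."""

    label: str
    times: np.ndarray           # distinct event times
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float               # nan = not reached
    n: int
    n_events: int


@dataclass(frozen=True)
class KmCurve:
    """Kaplan-Meier curves for the two levels of a binary covariate."""

    groups: dict                # label -> KmGroup

    def median_survival(self) -> dict:
        return {label: g.median for label, g in self.groups.items()}


def _km_one_group(time, event, label: str, conf_level: float = 0.95) -> KmGroup:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e])
    n_at_risk = np.array([(t >= u).sum() for u in uniq], dtype=float)
    d = np.array([((t == u) & e).sum() for u in uniq], dtype=float)
    surv = np.cumprod(1.0 - d / n_at_risk) if uniq.size else np.array([])
    # Greenwood variance of log S, CI on the log scale: S * exp(+/- z se)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf)
        se_log = np.sqrt(np.cumsum(terms))
        lo = surv * np.exp(-z * se_log)
        hi = np.minimum(surv * np.exp(z * se_log), 1.0)
    lo = np.where(surv > 0, lo, 0.0)
    hi = np.where(surv > 0, hi, 0.0)
    reached = np.flatnonzero(surv <= 0.5)
    median = float(uniq[reached[0]]) if reached.size else float("nan")
    return KmGroup(label=label, times=uniq, survival=surv,
                   ci_lower=lo, ci_upper=hi, median=median,
                   n=int(t.size), n_events=int(e.sum()))


def kaplan_meier(time, event, group, labels=("negative", "positive"),
                 conf_level: float = 0.95) -> KmCurve:
    """Product-limit curves for the two levels of a binary group indicator.

    Greenwood variance with a log-transformed CI; the median is the
    smallest event time with survival <= 0.5, NaN when never reached.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    groups = {}
    for level, label in zip((0, 1), labels):
        sel = group == level
        if not sel.any():
            raise ValueError(f"empty group: {label}")
        groups[label] = _km_one_group(time[sel], event[sel], label,
                                      conf_level=conf_level)
    return KmCurve(groups=groups)


def km_frame(curve: KmCurve) -> pd.DataFrame:
    """Tidy table of a :class:`KmCurve` (one row per group x event time)."""
    rows = []
    for label, g in curve.groups.items():
        for t, s, lo, hi in zip(g.times, g.survival, g.ci_lower, g.ci_upper):
            rows.append({"group": label, "time": t, "survival": s,
                         "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows, columns=["group", "time", "survival",
                                       "ci_lower", "ci_upper"])


def plot_km(curve: KmCurve, ax=None, title: str = ""):
    """Step plot of both strata with CI bands and median-survival markers."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    for label, g in curve.groups.items():
        t = np.concatenate([[0.0], g.times])
        s = np.concatenate([[1.0], g.survival])
        line, = ax.step(t, s, where="post", label=f"{label} (n={g.n})")
        lo = np.concatenate([[1.0], g.ci_lower])
        hi = np.concatenate([[1.0], g.ci_upper])
        ax.step(t, lo, where="post", linestyle="--", linewidth=0.8,
                color=line.get_color())
        ax.step(t, hi, where="post", linestyle="--", linewidth=0.8,
                color=line.get_color())
        if np.isfinite(g.median):
            ax.axvline(g.median, color="black", linestyle=":", linewidth=0.8)
    ax.set_xlabel("days from inclusion")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


# ---------------------------------------------------------------------------
# Endpoint orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Tuning of the survival chain."""

    threshold: float = 0.1
    gamma: float = 1.0
    n_folds: int = 5
    seed: int = 0
    ridge_init: float = 0.1
    n_lambda: int = 40
    lambda_min_ratio: float = 1e-3


@dataclass
class EndpointReport:
    """Full statistical report for one endpoint (PFS or OS)."""

    endpoint: str
    univariate: dict            # covariate name -> CoxResult
    screened: tuple             # ADC RSD covariates entering the aLASSO
    excluded: dict              # covariate -> reason (e.g. incomplete MGMT)
    fg: FarrarGlauberResult
    alasso: AlassoResult
    km: dict                    # selected covariate -> KmCurve

    def table(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.univariate.values()]
        return pd.DataFrame(rows).set_index("name")


def run_endpoint_analysis(rsd_df: pd.DataFrame, endpoint: str,
                          config: AnalysisConfig = AnalysisConfig()) -> EndpointReport:
    """Run screening -> Farrar-Glauber -> adaptive LASSO -> KM for one endpoint.

    ``rsd_df`` is the design table from
    :func:`adcsurv.longitudinal.rsd_table`. MGMT status is screened
    univariately on complete cases but excluded from the multivariable
    selection whenever it is missing for any subject (the exclusion is
    logged); treatment is screened alongside. The adaptive LASSO runs on
    the screened ADC RSD covariates.
    """
    from .features import METRIC_NAMES

    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    tcol, ecol = (("pfs_days", "pfs_event") if endpoint == "PFS"
                  else ("os_days", "os_event"))
    time = rsd_df[tcol].to_numpy(dtype=float)
    event = rsd_df[ecol].to_numpy(dtype=bool)

    rsd_cols = [f"{m}_rsd" for m in METRIC_NAMES]
    univariate = {}
    for col in rsd_cols + ["mgmt", "treatment"]:
        if col not in rsd_df.columns:
            continue
        vals = rsd_df[col]
        ok = vals.notna().to_numpy()
        if not ok.any():
            continue
        try:
            univariate[col] = cox_univariate(
                vals.to_numpy(dtype=float)[ok], time[ok], event[ok], name=col)
        except (ValueError, ConvergenceError) as exc:
            logger.warning("univariate Cox skipped for %s: %s", col, exc)

    try:
        fg = farrar_glauber(rsd_df[rsd_cols].to_numpy(dtype=float), names=rsd_cols)
    except (np.linalg.LinAlgError, ValueError) as exc:
        # perfectly collinear RSD design (possible in noiseless synthetic
        # cohorts) or fewer subjects than covariates; the diagnostic is
        # reported as degenerate, not fatal
        logger.warning("Farrar-Glauber test degenerate: %s", exc)
        fg = None

    adc_results = [univariate[c] for c in rsd_cols if c in univariate]
    screened = tuple(screen_covariates(adc_results, threshold=config.threshold))
    excluded = {}
    if "mgmt" in rsd_df.columns and rsd_df["mgmt"].isna().any():
        n_missing = int(rsd_df["mgmt"].isna().sum())
        excluded["mgmt"] = f"missing for {n_missing} subjects"
        logger.info("MGMT excluded from multivariable selection: %s",
                    excluded["mgmt"])

    if screened:
        Xs = rsd_df[list(screened)].to_numpy(dtype=float)
        alasso = alasso_cox(
            Xs, time, event, names=screened, gamma=config.gamma,
            n_folds=config.n_folds, seed=config.seed,
            ridge_init=config.ridge_init, n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
    else:
        alasso = AlassoResult(
            names=(), selected=(), coefficients={}, weights={},
            lambda_grid=np.array([]), lambda_chosen=float("nan"),
            cv_partial_loglik=np.array([]), refits={},
        )

    km = {}
    for name in alasso.selected:
        km[name] = kaplan_meier(time, event, rsd_df[name].to_numpy(dtype=int))

    return EndpointReport(endpoint=endpoint, univariate=univariate,
                          screened=screened, excluded=excluded,
                          fg=fg, alasso=alasso, km=km)
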