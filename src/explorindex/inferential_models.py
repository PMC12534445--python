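"""From-scratch inferential machinery behind the exploration analysis.

Implements the estimators the analysis relies on, without delegating to a
statistics package: ordinary least squares, robust regression with Huber's
M-estimator (IRLS, median-absolute-deviation scale, sandwich-type standard
errors with Huber's small-sample correction), the Mann-Whitney U test with
an exact enumerated null for small samples, maximum-likelihood logistic
regression by Newton-Raphson, and the one-way random-intercept variance
components model (REML and ANOVA estimators) yielding the intraclass
correlation coefficient.

Conventions follow the mainstream Python statistics stack so results are
directly comparable with it: Huber tuning constant c = 1.345, residual
scale = median(|r|)/Phi^{-1}(3/4) recomputed every iteration, z-statistics
and confidence intervals from the normal reference distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Term",
    "ModelFit",
    "RankTestResult",
    "VarianceComponents",
    "SeparationError",
    "ConvergenceError",
    "ols_fit",
    "huber_fit",
    "logistic_fit",
    "mann_whitney_u",
    "icc_one_way",
]

_MAD_CONST = float(stats.norm.ppf(0.75))  # 0.6745; 1/0.6745 = 1.4826


class SeparationError(ValueError):
    """Logistic outcome perfectly separated by a covariate."""


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class Term:
    name: str
    estimate: float
    std_error: float
    z_value: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass
class ModelFit:
    """Coefficient table plus fit metadata for any regression."""

    terms: list[Term]
    n_obs: int
    converged: bool = True
    n_iter: int = 0
    scale: float = float("nan")
    method: str = ""
    trace: list = field(default_factory=list, repr=False)

    def __getitem__(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def params(self) -> np.ndarray:
        return np.array([t.estimate for t in self.terms])

    @property
    def bse(self) -> np.ndarray:
        return np.array([t.std_error for t in self.terms])


@dataclass
class RankTestResult:
    u_statistic: float  # larger orientation
    u_min: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    tie_correction: bool


@dataclass
class VarianceComponents:
    sigma2_between: float
    sigma2_within: float
    icc: float
    n_groups: int
    method: str  # "reml" | "anova"


def _make_terms(
    names: Sequence[str], est: np.ndarray, se: np.ndarray, level: float = 0.95
) -> list[Term]:
    q = stats.norm.ppf(0.5 + level / 2)
    terms = []
    for nm, b, s in zip(names, est, se):
        if s > 0:
            z = b / s
            p = 2 * stats.norm.sf(abs(z))
        else:
            z = math_inf_sign(b)
            p = 0.0 if b != 0 else 1.0
        terms.append(Term(nm, float(b), float(s), float(z), float(p), float(b - q * s), float(b + q * s)))
    return terms


def math_inf_sign(b: float) -> float:
    return float(np.inf) if b >= 0 else float(-np.inf)


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify offending columns through pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, pivoting=True)
        bad = sorted(piv[rank:])
        cols = ", ".join(names[j] for j in bad)
        raise np.linalg.LinAlgError(f"design matrix rank-deficient; collinear column(s): {cols}")


def _default_names(p: int, names: Optional[Sequence[str]]) -> list[str]:
    if names is None:
        return [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names length must match number of columns")
    return list(names)


# ---------------------------------------------------------------------------
# Least squares
# ---------------------------------------------------------------------------


def ols_fit(y: Sequence[float], X: np.ndarray, names: Optional[Sequence[str]] = None) -> ModelFit:
    """Ordinary least squares with classical standard errors.

    ``X`` is the full design matrix (include an intercept column yourself).
    p-values and confidence intervals use the normal reference distribution,
    matching the z-value convention used throughout this package.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = _default_names(X.shape[1], names)
    _check_design(X, names)
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return ModelFit(
        terms=_make_terms(names, beta, se),
        n_obs=n,
        converged=True,
        n_iter=1,
        scale=float(np.sqrt(sigma2)),
        method="ols",
    )


# ---------------------------------------------------------------------------
# Huber robust regression
# ---------------------------------------------------------------------------


def _huber_psi(u: np.ndarray, c: float) -> np.ndarray:
    return np.clip(u, -c, c)


def huber_fit(
    y: Sequence[float],
    X: np.ndarray,
    c: float = 1.345,
    names: Optional[Sequence[str]] = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> ModelFit:
    """Huber M-estimator regression via iteratively reweighted least squares.

    The residual scale is the standardized MAD about zero,
    median(|r|)/0.6745, recomputed at every iteration.  Standard errors use
    the sandwich form with Huber's degrees-of-freedom correction
    (the "H1" covariance of the mainstream stack), so that for well-behaved
    data the full coefficient table agrees with it to numerical precision.
    With c -> infinity the psi-function is linear everywhere and the fit
    reduces to OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = _default_names(X.shape[1], names)
    _check_design(X, names)
    n, p = X.shape

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    trace: list[np.ndarray] = [beta.copy()]
    converged = False
    scale = float("nan")
    ols_scale_fallback = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        scale = float(np.median(np.abs(resid)) / _MAD_CONST)
        if scale == 0:
            # degenerate residual distribution: fall back to the OLS scale
            rss = float(resid @ resid)
            scale = float(np.sqrt(rss / (n - p))) if rss > 0 else 1.0
            ols_scale_fallback = True
            warnings.warn(
                "zero MAD of residuals; falling back to OLS residual scale",
                RuntimeWarning,
                stacklevel=2,
            )
            if rss == 0:  # exact fit: nothing left to reweight
                converged = True
                break
        u = resid / scale
        w = np.ones_like(u)
        big = np.abs(u) > c
        w[big] = c / np.abs(u[big])
        sw = np.sqrt(w)
        beta_new = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
        trace.append(beta_new.copy())
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    resid = y - X @ beta
    if not ols_scale_fallback:
        scale = float(np.median(np.abs(resid)) / _MAD_CONST)
        if scale == 0:
            scale = float(np.sqrt(resid @ resid / (n - p))) or 1.0
    u = resid / scale
    psi = _huber_psi(u, c)
    dpsi = (np.abs(u) <= c).astype(float)
    m1 = float(np.mean(dpsi))
    if m1 == 0:
        raise ConvergenceError("all observations downweighted to the boundary", trace)
    k = 1.0 + (p / n) * float(np.var(dpsi)) / m1**2
    cov = (
        k**2
        * (np.sum((psi * scale) ** 2) / (n - p))
        / m1**2
        * np.linalg.inv(X.T @ X)
    )
    se = np.sqrt(np.diag(cov))
    if not converged:
        warnings.warn(
            f"Huber IRLS did not converge in {max_iter} iterations; "
            "returning last iterate (converged=False)",
            RuntimeWarning,
            stacklevel=2,
        )
    return ModelFit(
        terms=_make_terms(names, beta, se),
        n_obs=n,
        converged=converged,
        n_iter=it,
        scale=scale,
        method="huber",
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


def _check_separation(y: np.ndarray, X: np.ndarray, names: Sequence[str]) -> None:
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):  # intercept-like column cannot separate
            continue
        x0, x1 = col[y == 0], col[y == 1]
        if x0.size and x1.size and (x0.max() <= x1.min() or x1.max() <= x0.min()):
            raise SeparationError(
                f"outcome perfectly separated by covariate {names[j]!r}"
            )


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_fit(
    y: Sequence[int],
    X: np.ndarray,
    names: Optional[Sequence[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> ModelFit:
    """Binary logistic regression by Newton-Raphson with step halving.

    Standard errors come from the observed information at the optimum; the
    log-likelihood is guaranteed non-decreasing across iterations by halving
    the Newton step when needed.  Perfect separation by a single covariate
    is detected up front and raised as :class:`SeparationError`.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = _default_names(X.shape[1], names)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need >= 2 observations in each outcome class")
    _check_design(X, names)
    _check_separation(y, X, names)

    n, p = X.shape
    beta = np.zeros(p)
    ll = _log_likelihood(y, X @ beta)
    trace = [beta.copy()]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}", trace) from exc
        # step halving keeps the log-likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _log_likelihood(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        beta_new = beta + factor * step
        trace.append(beta_new.copy())
        delta = np.max(np.abs(beta_new - beta))
        beta, ll = beta_new, _log_likelihood(y, X @ beta_new)
        if np.max(np.abs(beta)) > 1e4:
            raise SeparationError(
                "coefficients diverging; outcome may be (quasi-)separated by "
                f"covariate {names[int(np.argmax(np.abs(beta)))]!r}"
            )
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations", trace)

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = (X * (mu * (1 - mu))[:, None]).T @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return ModelFit(
        terms=_make_terms(names, beta, se),
        n_obs=n,
        converged=True,
        n_iter=it,
        scale=1.0,
        method="logistic",
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 20  # combined sample size for the enumerated null


def _exact_rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """Distribution of the rank sum of sample 1 under the null.

    counts[s] = number of ways to pick n1 of the ranks 1..n1+n2 with sum s
    (dynamic programming over ranks; no ties assumed).
    """
    N = n1 + n2
    max_sum = n1 * N - n1 * (n1 - 1) // 2
    # dp[j][s]: ways to choose j ranks so far with sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for j in range(min(r, n1), 0, -1):
            dp[j, r:] += dp[j - 1, : max_sum + 1 - r]
    return dp[n1]


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Midranks handle ties.  Both orientations of U are reported
    (``u_statistic`` is the larger; ``u_statistic + u_min = n1*n2``).  The
    p-value is exact by full enumeration of the rank-sum null when the
    combined sample size is at most 20 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = n1 * n2 - u1
    u_max, u_min = max(u1, u2), min(u1, u2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n1 + n2 <= _EXACT_LIMIT and not has_ties:
        counts = _exact_rank_sum_counts(n1, n2)
        total = counts.sum()
        # U1 = R1 - n1(n1+1)/2; tail prob of the larger orientation
        sums = np.arange(counts.size)
        u_of_sum = sums - n1 * (n1 + 1) / 2
        p = 2.0 * counts[u_of_sum >= u_max].sum() / total
        return RankTestResult(u_max, u_min, float(min(1.0, p)), "exact", False)

    N = n1 + n2
    mu = n1 * n2 / 2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1)) if N > 1 else 0.0
    sigma2 = n1 * n2 / 12 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        # all observations identical: no evidence either way
        return RankTestResult(u_max, u_min, 1.0, "normal_approx", has_ties)
    z = (u_max - mu - 0.5) / np.sqrt(sigma2)
    p = float(min(1.0, 2 * stats.norm.sf(z)))
    return RankTestResult(u_max, u_min, p, "normal_approx", has_ties)


# ---------------------------------------------------------------------------
# One-way random-intercept variance components / ICC
# ---------------------------------------------------------------------------


def _anova_components(values: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float]:
    """Method-of-moments (one-way ANOVA) estimator for unbalanced designs."""
    a = len(groups)
    N = values.size
    gm = values.mean()
    ns = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(ns * (means - gm) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (a - 1)
    if N - a == 0:
        raise ValueError("every group has a single observation; within variance unidentifiable")
    msw = ssw / (N - a)
    n0 = (N - float(np.sum(ns**2)) / N) / (a - 1)
    sigma2_b = max(0.0, (msb - msw) / n0)
    return sigma2_b, msw


def icc_one_way(
    values: Sequence[float],
    group_ids: Sequence[object],
    method: str = "reml",
) -> VarianceComponents:
    """Intraclass correlation from the one-way random-intercept model.

    Model: y_ij = mu + b_i + e_ij with b_i ~ N(0, sigma2_between) shared
    within group i and e_ij ~ N(0, sigma2_within).  The REML fit profiles
    the criterion down to a one-dimensional optimization over the variance
    ratio lambda = sigma2_between/sigma2_within, which handles unbalanced
    group sizes exactly; the ANOVA (method-of-moments) estimator is
    available as an independent cross-check.  Negative component estimates
    are truncated at zero, so icc lies in [0, 1].
    """
    values = np.asarray(values, dtype=float)
    group_ids = np.asarray(group_ids)
    if values.size != group_ids.size:
        raise ValueError("values and group_ids must have equal length")
    uniq = np.unique(group_ids)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups for a variance-components model")
    groups = [values[group_ids == g] for g in uniq]

    if method == "anova":
        s2b, s2w = _anova_components(values, groups)
        icc = s2b / (s2b + s2w) if (s2b + s2w) > 0 else 0.0
        return VarianceComponents(s2b, s2w, float(np.clip(icc, 0, 1)), uniq.size, "anova")
    if method != "reml":
        raise ValueError("method must be 'reml' or 'anova'")

    N = values.size
    ns = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    if N - len(groups) == 0:
        raise ValueError("every group has a single observation; within variance unidentifiable")
    if ssw == 0.0 and float(np.var(means)) > 0.0:
        # no within-group variation at all: the grouping explains everything
        s2b, _ = _anova_components(values, groups)
        return VarianceComponents(s2b, 0.0, 1.0, uniq.size, "reml")

    def neg2_reml_profiled(lam: float) -> float:
        w = ns / (1.0 + ns * lam)
        mu_hat = float(np.sum(w * means) / np.sum(w))
        q = ssw + float(np.sum(w * (means - mu_hat) ** 2))
        return (
            (N - 1) * np.log(q)
            + float(np.sum(np.log1p(ns * lam)))
            + np.log(float(np.sum(w)))
        )

    # coarse log-grid then local refinement; lambda = 0 is a valid boundary
    lams = np.concatenate([[0.0], np.logspace(-6, 4, 121)])
    vals = np.array([neg2_reml_profiled(l) for l in lams])
    i = int(np.argmin(vals))
    lo = lams[max(0, i - 1)]
    hi = lams[min(len(lams) - 1, i + 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            neg2_reml_profiled, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        lam = float(res.x) if res.fun <= vals[i] else float(lams[i])
    else:
        lam = float(lams[i])
    if neg2_reml_profiled(0.0) <= neg2_reml_profiled(lam):
        lam = 0.0

    w = ns / (1.0 + ns * lam)
    mu_hat = float(np.sum(w * means) / np.sum(w))
    q = ssw + float(np.sum(w * (means - mu_hat) ** 2))
    s2w = q / (N - 1)
    s2b = lam * s2w
    icc = lam / (1.0 + lam)
    return VarianceComponents(float(s2b), float(s2w), float(np.clip(icc, 0, 1)), uniq.size, "reml")
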