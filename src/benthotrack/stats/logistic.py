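"""Logistic regression with a per-individual random intercept.

The model is ``logit P(y_ij = 1) = x_ij' beta + b_i`` with iid
``b_i ~ N(0, sigma2)``. The marginal likelihood is approximated by
Laplace's method: for a candidate ``sigma2`` the joint penalized
log-likelihood in (beta, b) is maximized by Newton iteration (an
L2 penalty ``sum b_i^2 / (2 sigma2)`` on the group intercepts), and the
approximate marginal log-likelihood

    l_pen(beta_hat, b_hat) - (1/2) sum_i log(1 + sigma2 * h_i)

(h_i the unpenalized curvature in b_i at the mode) is maximized over
``log sigma2`` by bounded 1-D search. This is exactly ridge-penalized
group intercepts at the optimal penalty, which is all the intercept-only
random effect requires.

Standard errors for beta come from the beta block of the inverse joint
penalized information at the optimum.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .clogit import FitResult, SeparationError

_BOUND = 15.0  # |beta| beyond this is treated as separation


def _expit(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _penalized_newton(y, X, gidx, n_groups, sigma2, beta0, b0, terms,
                      tol=1e-10, max_iter=200):
    """Maximize the sigma2-penalized joint log-likelihood in (beta, b)."""
    p = X.shape[1]
    beta = beta0.copy()
    b = b0.copy()
    for _ in range(max_iter):
        eta = X @ beta + b[gidx]
        mu = _expit(eta)
        r = y - mu
        g_beta = X.T @ r
        g_b = np.bincount(gidx, weights=r, minlength=n_groups) - b / sigma2
        grad_norm = max(np.max(np.abs(g_beta)), np.max(np.abs(g_b)))
        if grad_norm < tol:
            break
        w = mu * (1.0 - mu)
        # Joint Hessian blocks: A = X'WX, D = diag(group sums of w) + I/sigma2,
        # B = X'W Z (p x g). Solve by Schur complement on the diagonal D block.
        A = (X * w[:, None]).T @ X
        d = np.bincount(gidx, weights=w, minlength=n_groups) + 1.0 / sigma2
        Bmat = np.zeros((p, n_groups))
        for j in range(p):
            Bmat[j] = np.bincount(gidx, weights=w * X[:, j], minlength=n_groups)
        S = A - (Bmat / d) @ Bmat.T
        rhs = g_beta - Bmat @ (g_b / d)
        try:
            step_beta = np.linalg.solve(S + 1e-12 * np.eye(p), rhs)
        except np.linalg.LinAlgError:
            step_beta = np.linalg.lstsq(S, rhs, rcond=None)[0]
        step_b = (g_b - Bmat.T @ step_beta) / d
        # step-halving on the penalized objective
        def obj(bt, bb):
            e = X @ bt + bb[gidx]
            ll = float(y @ e - np.logaddexp(0.0, e).sum())
            return ll - float(bb @ bb) / (2.0 * sigma2)
        cur = obj(beta, b)
        t = 1.0
        for _ in range(30):
            nb, nbb = beta + t * step_beta, b + t * step_b
            if obj(nb, nbb) >= cur - 1e-12:
                break
            t /= 2.0
        beta, b = nb, nbb
        if np.max(np.abs(beta)) > _BOUND:
            worst = terms[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"coefficient for term {worst!r} exceeded |beta| = {_BOUND}: "
                "likely complete separation"
            )
    eta = X @ beta + b[gidx]
    mu = _expit(eta)
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    pen_ll = ll - float(b @ b) / (2.0 * sigma2)
    h = np.bincount(gidx, weights=mu * (1.0 - mu), minlength=n_groups)
    laplace = pen_ll - 0.5 * np.sum(np.log1p(sigma2 * h))
    return beta, b, laplace, grad_norm < 1e-6


def fit_logistic_re(
    y,
    X,
    groups,
    terms: list[str] | None = None,
    fixed_variance: float | None = None,
    log_sigma2_bounds: tuple[float, float] = (-12.0, 6.0),
) -> tuple[FitResult, float]:
    """Fit a logistic regression with a random intercept per group.

    Parameters
    ----------
    y : binary response.
    X : (n, p) design matrix *including* the intercept column.
    groups : group (individual) labels, one per row.
    fixed_variance : if given, skip the variance search and fit at this
        sigma2 (used for invariance tests and as a profiling tool).

    Returns
    -------
    (FitResult, sigma2_hat)
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    uniq, gidx = np.unique(groups, return_inverse=True)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError(f"need at least 2 groups, got {n_groups}")
    p = X.shape[1]
    terms = list(terms) if terms is not None else [f"x{j}" for j in range(p)]
    # Constant non-intercept columns are unidentifiable alongside the intercept
    const = np.all(X == X[0], axis=0)
    if const.sum() > 1:
        bad = [t for t, c in zip(terms, const) if c][1:]
        raise ValueError(f"constant columns besides the intercept: {bad}")

    beta0 = np.zeros(p)
    b0 = np.zeros(n_groups)

    if fixed_variance is not None:
        sigma2 = float(fixed_variance)
        beta, b, laplace, conv = _penalized_newton(
            y, X, gidx, n_groups, sigma2, beta0, b0, terms
        )
    else:
        cache: dict[float, tuple] = {}

        def neg_marginal(log_s2: float) -> float:
            s2 = float(np.exp(log_s2))
            res = _penalized_newton(y, X, gidx, n_groups, s2, beta0, b0, terms)
            cache[log_s2] = res
            return -res[2]

        opt = minimize_scalar(
            neg_marginal, bounds=log_sigma2_bounds, method="bounded",
            options={"xatol": 1e-6},
        )
        sigma2 = float(np.exp(opt.x))
        beta, b, laplace, conv = cache[opt.x]

    # SEs: beta block of the inverse joint penalized information
    eta = X @ beta + b[gidx]
    mu = _expit(eta)
    w = mu * (1.0 - mu)
    A = (X * w[:, None]).T @ X
    d = np.bincount(gidx, weights=w, minlength=n_groups) + 1.0 / sigma2
    Bmat = np.zeros((p, n_groups))
    for j in range(p):
        Bmat[j] = np.bincount(gidx, weights=w * X[:, j], minlength=n_groups)
    S = A - (Bmat / d) @ Bmat.T
    se = None
    try:
        cov = np.linalg.inv(S)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        pass
    fit = FitResult(
        terms=terms,
        beta=beta,
        se=se,
        loglik=float(laplace),
        converged=bool(conv),
        n_iter=0,
        n_strata=n_groups,
    )
    return fit, sigma2
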