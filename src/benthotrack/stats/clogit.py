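"""Stratified conditional logistic regression by Newton-Raphson.

The conditional (partial) likelihood for strata of one case and m controls
is the softmax likelihood

    l(beta) = sum_s [ eta_case(s) - log sum_{j in s} exp(eta_j) ],

with eta = X beta. Gradient and Hessian are analytic:

    g = X'(y - p),   H = -(X' diag(p) X - M'M),

where p are the within-stratum choice probabilities and M stacks the
per-stratum probability-weighted covariate means. Covariates with no
within-stratum variation anywhere contribute nothing to the conditional
likelihood and are dropped (and reported) before fitting. Diverging
coefficients (|beta| > 15) are treated as separation and raised as an
error naming the offending term rather than returned silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: Coefficient magnitude beyond which the fit is declared separated.
SEPARATION_BOUND: float = 15.0


class SeparationError(RuntimeError):
    """The conditional likelihood has no finite maximizer."""


class DegenerateDesignError(ValueError):
    """No covariate varies within any stratum."""


@dataclass
class FitResult:
    """Point fit of a (conditional) logistic model."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    dropped_terms: list[str] = field(default_factory=list)
    n_strata: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": self.terms,
                "beta": [float(b) for b in self.beta],
                "se": None if self.se is None else [float(s) for s in self.se],
                "loglik": float(self.loglik),
                "converged": self.converged,
                "n_iter": self.n_iter,
                "dropped_terms": self.dropped_terms,
                "n_strata": self.n_strata,
            }
        )


def _prepare(X, y, strata):
    """Sort rows by stratum, validate the 1-case-per-stratum invariant."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if X.ndim != 2 or X.shape[0] != y.size or strata.size != y.size:
        raise ValueError("X, y and strata must have matching first dimensions")
    if strata.dtype.kind in "iu" and (
        strata.size < 2 or np.all(strata[1:] >= strata[:-1])
    ):
        # already grouped (the common case in resampling loops)
        boundaries = np.flatnonzero(np.diff(strata)) + 1
        starts = np.concatenate([[0], boundaries])
        counts = np.diff(np.concatenate([starts, [strata.size]]))
        uniq = strata[starts]
    else:
        order = np.argsort(strata, kind="stable")
        X, y, strata = X[order], y[order], strata[order]
        uniq, starts, counts = np.unique(strata, return_index=True, return_counts=True)
    cases = np.add.reduceat(y, starts)
    if not np.allclose(cases, 1.0):
        bad = uniq[np.argmax(np.abs(cases - 1.0))]
        raise ValueError(f"each stratum needs exactly one case; stratum {bad!r} has {cases[np.argmax(np.abs(cases-1.0))]:.0f}")
    return X, y, starts, counts, uniq


def _within_stratum_varying(X, starts, counts):
    """Boolean mask of columns that vary within at least one stratum."""
    first = np.repeat(X[starts], counts, axis=0)
    return np.any(X != first, axis=0)


def _stratum_softmax(eta, starts, counts):
    """Within-stratum softmax probabilities and per-stratum log-sum-exp."""
    m = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - np.repeat(m, counts))
    denom = np.add.reduceat(z, starts)
    p = z / np.repeat(denom, counts)
    lse = m + np.log(denom)
    return p, lse


def clogit_loglik(beta, X, y, starts, counts):
    eta = X @ beta
    _, lse = _stratum_softmax(eta, starts, counts)
    return float(y @ eta - lse.sum())


def fit_clogit(
    X,
    y,
    strata,
    terms: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    beta0: np.ndarray | None = None,
) -> FitResult:
    """Fit a stratified conditional logistic regression.

    Parameters
    ----------
    X : (n, p) design matrix (no intercept; it is stratum-constant).
    y : binary case indicator, exactly one 1 per stratum.
    strata : stratum labels, one per row.
    terms : column names; defaults to ``x0..x{p-1}``.

    Returns
    -------
    FitResult with dropped (within-stratum-constant) terms recorded.
    """
    X, y, starts, counts, uniq = _prepare(X, y, strata)
    p_cols = X.shape[1]
    terms = list(terms) if terms is not None else [f"x{j}" for j in range(p_cols)]
    if len(terms) != p_cols:
        raise ValueError("terms length must match number of columns")

    varying = _within_stratum_varying(X, starts, counts)
    dropped = [t for t, v in zip(terms, varying) if not v]
    kept = [t for t, v in zip(terms, varying) if v]
    Xv = X[:, varying]
    if Xv.shape[1] == 0:
        raise DegenerateDesignError(
            "no covariate varies within any stratum; conditional likelihood is flat"
        )

    if beta0 is not None:
        beta = np.nan_to_num(np.asarray(beta0, dtype=float)[varying]).copy()
    else:
        beta = np.zeros(Xv.shape[1])
    ll = clogit_loglik(beta, Xv, y, starts, counts)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        eta = Xv @ beta
        p, _ = _stratum_softmax(eta, starts, counts)
        grad = Xv.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        Xp = Xv * p[:, None]
        M = np.add.reduceat(Xp, starts, axis=0)  # per-stratum weighted means
        H = Xv.T @ Xp - M.T @ M  # negative Hessian
        # Levenberg damping for near-singular information
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        if np.max(np.abs(step)) < 0.5:
            # near the optimum the full Newton step is safe; skip the
            # line search (each probe costs a log-likelihood pass)
            beta = beta + step
            ll = clogit_loglik(beta, Xv, y, starts, counts)
        else:
            # step-halving line search on the log-likelihood
            t = 1.0
            for _ in range(30):
                beta_new = beta + t * step
                ll_new = clogit_loglik(beta_new, Xv, y, starts, counts)
                if ll_new >= ll - 1e-12:
                    break
                t /= 2.0
            beta, ll = beta_new, ll_new
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            worst = kept[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"coefficient for term {worst!r} exceeded |beta| = {SEPARATION_BOUND}: "
                "likely complete or quasi-complete separation within strata"
            )
    else:
        converged = False

    se = None
    if converged:
        eta = Xv @ beta
        p, _ = _stratum_softmax(eta, starts, counts)
        Xp = Xv * p[:, None]
        M = np.add.reduceat(Xp, starts, axis=0)
        H = Xv.T @ Xp - M.T @ M
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = None

    # re-expand to the full term list with NaN for dropped columns
    beta_full = np.full(p_cols, np.nan)
    beta_full[varying] = beta
    se_full = None
    if se is not None:
        se_full = np.full(p_cols, np.nan)
        se_full[varying] = se
    return FitResult(
        terms=terms,
        beta=beta_full,
        se=se_full,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        dropped_terms=dropped,
        n_strata=len(uniq),
    )


@dataclass
class BootstrapResult:
    """Stratum-resampling bootstrap summary of a conditional fit."""

    terms: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    n_failed: int
    draws: np.ndarray | None = None  # (B_ok, p) converged replicate estimates

    def percentile_interval(self, level: float = 0.95):
        """Per-term percentile interval over converged replicates."""
        if self.draws is None:
            raise ValueError("bootstrap draws were not retained")
        a = (1.0 - level) / 2.0
        lo = np.nanpercentile(self.draws, 100 * a, axis=0)
        hi = np.nanpercentile(self.draws, 100 * (1 - a), axis=0)
        return lo, hi


def bootstrap_clogit(
    X,
    y,
    strata,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    terms: list[str] | None = None,
    keep_draws: bool = True,
    max_failure_fraction: float = 0.2,
    warm_start: bool = True,
) -> BootstrapResult:
    """Bootstrap a conditional logistic fit by resampling *strata*.

    Strata (not rows) are drawn with replacement B times and the model is
    refit to each replicate (warm-started at the full-data point estimate
    unless ``warm_start=False``). Replicates that separate or fail to
    converge are dropped and counted; more than ``max_failure_fraction``
    failures raises, flagging an unstable fit.
    """
    X, y, starts, counts, uniq = _prepare(X, y, strata)
    if len(uniq) < 10:
        raise ValueError(f"need at least 10 strata to bootstrap, got {len(uniq)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_cols = X.shape[1]
    terms = list(terms) if terms is not None else [f"x{j}" for j in range(p_cols)]
    k = len(uniq)
    beta0 = None
    if warm_start:
        full_strata = np.repeat(np.arange(k), counts)
        try:
            beta0 = fit_clogit(X, y, full_strata, terms=terms).beta
        except (SeparationError, DegenerateDesignError):
            beta0 = None
    estimates = []
    n_failed = 0
    for _ in range(B):
        pick = rng.integers(0, k, size=k)
        lengths = counts[pick]
        cum = np.cumsum(lengths)
        within = np.arange(cum[-1]) - np.repeat(cum - lengths, lengths)
        idx = np.repeat(starts[pick], lengths) + within
        new_strata = np.repeat(np.arange(k), lengths)
        try:
            fit = fit_clogit(
                X[idx], y[idx], new_strata, terms=terms, beta0=beta0, tol=1e-8
            )
        except (SeparationError, DegenerateDesignError):
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        estimates.append(fit.beta)
    if n_failed > max_failure_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to converge: "
            "the fit is unstable (likely near-separation in some strata)"
        )
    est = np.asarray(estimates)
    mean = np.nanmean(est, axis=0)
    sd = np.nanstd(est, axis=0, ddof=1)
    return BootstrapResult(
        terms=terms,
        mean=mean,
        sd=sd,
        n_replicates=len(estimates),
        n_failed=n_failed,
        draws=est if keep_draws else None,
    )
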