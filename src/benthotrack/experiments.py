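"""Verification experiments: parameter recovery, calibration, oracles.

The study's field results depend on proprietary positioning data, so the
pipeline is validated by properties that have known ground truth: exact
closed forms for the conditional likelihood, recovery of generating
parameters from synthetic tracks, calibration of null fits, and
determinism of the pipeline. Each experiment here builds its inputs from
scratch (seeded), runs the relevant package machinery, and returns the
measured quantities; both the test suite and the acceptance script call
these functions.

Problem sizes are chosen to give decisive Monte-Carlo evidence on a
single CPU in minutes: the step-selection recovery uses 5 individuals of
600 steps with 25 random steps per stratum and 150 bootstrap replicates
per fit, pooled across individuals sharing the generating coefficients
(pooling strata is licit in a conditional likelihood and the estimand is
unchanged). See docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import issf as issf_mod
from . import rsf as rsf_mod
from . import trackprep
from .qc import candidate_cutoff
from .raster import BenthoscapeRaster
from .simulate import (
    SimulationConfig,
    generate_benthoscape,
    generate_sync_tags,
    simulate_track,
    track_to_fixes,
    weighted_presences,
)
from .stats.clogit import (
    SeparationError,
    _prepare,
    bootstrap_clogit,
    clogit_loglik,
    fit_clogit,
)
from .stats.distributions import fit_gamma, fit_vonmises


# ---------------------------------------------------------------- clogit

def clogit_two_strata_beta() -> float:
    """Worked two-strata example whose conditional MLE is ln 2."""
    X = np.array([[1.0], [0.0], [0.0], [0.0], [1.0], [0.0]])
    y = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    strata = np.array([0, 0, 0, 1, 1, 1])
    return float(fit_clogit(X, y, strata).beta[0])


def clogit_grid_oracle_max_dev(seed: int, n_datasets: int = 10) -> float:
    """Largest |Newton MLE - grid-search maximizer| over random small
    stratified datasets (1 covariate, <= 20 strata, grid step 1e-3)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_datasets:
        n_strata = int(rng.integers(8, 21))
        m = int(rng.integers(2, 5))
        rows, ys, sids = [], [], []
        beta_true = rng.uniform(-1.5, 1.5)
        for s in range(n_strata):
            x = rng.normal(size=m + 1)
            p = np.exp(beta_true * x - (beta_true * x).max())
            p /= p.sum()
            case = rng.choice(m + 1, p=p)
            for j in range(m + 1):
                rows.append([x[j]])
                ys.append(1.0 if j == case else 0.0)
                sids.append(s)
        X, y, sid = np.array(rows), np.array(ys), np.array(sids)
        try:
            fit = fit_clogit(X, y, sid)
        except SeparationError:
            continue
        Xs, ys_, starts, counts, _ = _prepare(X, y, sid)
        grid = np.arange(-5.0, 5.0 + 1e-9, 1e-3)
        lls = np.array(
            [clogit_loglik(np.array([b]), Xs, ys_, starts, counts) for b in grid]
        )
        oracle = grid[int(np.argmax(lls))]
        worst = max(worst, abs(float(fit.beta[0]) - oracle))
        done += 1
    return worst


# ------------------------------------------------------- iSSF experiments

RECOVERY_BETA = {2: 1.0, 0: -0.5}
RECOVERY_RASTER_CFG = dict(
    n_rows=150, n_cols=150,
    proportions={0: 0.2, 1: 0.25, 2: 0.2, 3: 0.15, 4: 0.2},
    patchiness=15.0,
)


def _steps_for_individual(raster, beta, n_steps, rng, tag, n_candidates=100):
    # 100 simulation candidates per step: the generative discrete choice
    # approaches the continuous-availability model the fit assumes (at 20
    # candidates the finite choice set alone attenuates a beta of 1 by
    # ~0.07, at 50 by ~0.03; at 100 the gap is below Monte-Carlo
    # resolution while extra random steps at fixed candidates change
    # nothing — the gap is generative, not estimation-side)
    xmin, ymin, xmax, ymax = raster.bounds
    start = (
        xmin + (0.3 + 0.4 * rng.random()) * (xmax - xmin),
        ymin + (0.3 + 0.4 * rng.random()) * (ymax - ymin),
    )
    cfg = SimulationConfig()
    track = simulate_track(
        raster, cfg.kernel, beta, start, n_steps, seed=rng, tag_id=tag,
        n_candidates=n_candidates,
    )
    steps = trackprep.steps_from_fixes(track_to_fixes(track), rate=600, tolerance=1)
    return trackprep.attach_covariates(steps, raster)


def issf_recovery_replicate(
    seed: int,
    beta: dict[int, float] = RECOVERY_BETA,
    n_individuals: int = 5,
    n_steps: int = 600,
    n_random: int = 25,
    B: int = 200,
):
    """One recovery replicate: simulate, build strata, fit, bootstrap.

    Strata from all individuals (sharing the generating coefficients)
    are pooled into one conditional fit. Returns the estimates table.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_individuals + 2)
    raster = generate_benthoscape(
        SimulationConfig(**RECOVERY_RASTER_CFG), seed=children[-1]
    )
    frames = []
    offset = 0
    for i in range(n_individuals):
        rng = np.random.default_rng(children[i])
        steps = _steps_for_individual(raster, beta, n_steps, rng, f"BL {i:03d}")
        tentative = issf_mod.fit_tentative_kernel(steps)
        strata = issf_mod.draw_random_steps(
            steps, tentative, raster, n_random=n_random, seed=rng
        )
        strata["stratum"] = strata["stratum"] + offset
        offset = int(strata["stratum"].max()) + 1
        frames.append(strata)
    pooled = pd.concat(frames, ignore_index=True)
    X, y, sid, terms = issf_mod.build_issf_design(pooled, min_support=5)
    fit = fit_clogit(X, y, sid, terms=terms)
    boot = bootstrap_clogit(
        X, y, sid, B=B,
        seed=int(np.random.default_rng(children[-2]).integers(2**31)),
        terms=terms,
    )
    lo, hi = boot.percentile_interval(0.95)
    return pd.DataFrame(
        {"term": terms, "estimate": fit.beta, "se": fit.se,
         "pct_lo": lo, "pct_hi": hi}
    ).set_index("term")


def issf_recovery_experiment(seed: int, n_replicates: int = 50, **kw):
    """Bias and bootstrap-interval coverage of the end-class estimates
    over seeded replicates of the step-selection recovery."""
    beta = kw.pop("beta", RECOVERY_BETA)
    rows = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        est = issf_recovery_replicate(rep_seed, beta=beta, **kw)
        row = {}
        for cls, b in beta.items():
            term = f"end_{cls}"
            if term in est.index:
                row[f"est_{cls}"] = est.loc[term, "estimate"]
                row[f"cover_{cls}"] = bool(
                    est.loc[term, "pct_lo"] <= b <= est.loc[term, "pct_hi"]
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    out = {}
    for cls, b in beta.items():
        out[f"bias_{cls}"] = float(df[f"est_{cls}"].mean() - b)
        out[f"coverage_{cls}"] = float(df[f"cover_{cls}"].mean())
    out["n_replicates"] = len(df)
    return out


def issf_null_calibration(
    seed: int,
    n_replicates: int = 50,
    n_steps: int = 600,
    n_random: int = 25,
):
    """Size of the per-term Wald test under no selection.

    Each replicate simulates one individual with all coefficients zero,
    fits the conditional model, and records which end-class terms have
    Wald |z| > 1.96. Returns the per-term rejection rate (nominal 0.05)
    and the per-replicate any-term rejection fraction.
    """
    ss = np.random.SeedSequence(seed)
    n_tests = 0
    n_reject = 0
    any_reject = 0
    n_done = 0
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        raster = generate_benthoscape(
            SimulationConfig(**RECOVERY_RASTER_CFG),
            seed=int(rng.integers(2**31)),
        )
        steps = _steps_for_individual(raster, {}, n_steps, rng, "BL 000")
        tentative = issf_mod.fit_tentative_kernel(steps)
        strata = issf_mod.draw_random_steps(
            steps, tentative, raster, n_random=n_random, seed=rng
        )
        X, y, sid, terms = issf_mod.build_issf_design(strata, min_support=5)
        try:
            fit = fit_clogit(X, y, sid, terms=terms)
        except SeparationError:
            continue
        if not fit.converged or fit.se is None:
            continue
        z = np.abs(fit.beta / fit.se)
        endmask = np.array([t.startswith("end_") for t in terms])
        rejected = (z > 1.96) & endmask & np.isfinite(z)
        n_tests += int(np.sum(endmask & np.isfinite(z)))
        n_reject += int(rejected.sum())
        any_reject += int(rejected.any())
        n_done += 1
    return {
        "per_term_rejection_rate": n_reject / n_tests if n_tests else float("nan"),
        "any_term_rejection_fraction": any_reject / n_done if n_done else float("nan"),
        "n_replicates": n_done,
        "n_term_tests": n_tests,
    }


# -------------------------------------------------------- RSF experiments

def rsf_weighted_study(
    seed: int,
    weights: dict[int, float],
    n_individuals: int = 6,
    n_presences: int = 500,
    ratio: int = 10,
) -> pd.DataFrame:
    """Use-available data with known selection weights.

    Presences and pseudo-absences share an explicit availability domain
    (the raster extent inset by one patch margin) so the log weights are
    the exact estimand.
    """
    cfg = SimulationConfig(**RECOVERY_RASTER_CFG)
    raster = generate_benthoscape(cfg, seed=seed)
    margin = 5.0
    xmin, ymin, xmax, ymax = raster.bounds
    domain = box(xmin + margin, ymin + margin, xmax - margin, ymax - margin)
    frames = []
    ss = np.random.SeedSequence(seed + 1)
    children = ss.spawn(2 * n_individuals)
    for i in range(n_individuals):
        pres = weighted_presences(
            raster, weights, n_presences,
            seed=np.random.default_rng(children[2 * i]),
            tag_id=f"BL {i:03d}", margin=margin,
        )
        frames.append(
            rsf_mod.draw_pseudo_absences(
                pres, raster, ratio=ratio, domain=domain,
                seed=np.random.default_rng(children[2 * i + 1]),
            )
        )
    return pd.concat(frames, ignore_index=True)


def rsf_recovery_experiment(seed: int, reruns: int = 100):
    """Known-weights recovery and null calibration of the 100x100
    subsample-refit scheme. Returns median RSS per experiment."""
    ss = np.random.SeedSequence(seed)
    s1, s2, s3, s4 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    data = rsf_weighted_study(s1, weights={2: 3.0})
    coefs = rsf_mod.rsf_resample_fit(data, reruns=reruns, per_individual=100, seed=s2)
    rss_weighted = float(np.exp(coefs["substrate_2"].median()))
    data0 = rsf_weighted_study(s3, weights={})
    coefs0 = rsf_mod.rsf_resample_fit(data0, reruns=reruns, per_individual=100, seed=s4)
    null_rss = {
        col.split("_")[1]: float(np.exp(coefs0[col].median()))
        for col in coefs0.columns
        if col.startswith("substrate_")
    }
    return {
        "weighted_median_rss": rss_weighted,
        "null_rss": null_rss,
        "null_max_abs_log_rss": float(
            max(abs(np.log(v)) for v in null_rss.values())
        ),
        "n_reruns": reruns,
    }


# ----------------------------------------------------------- QC and kernels

def qc_exactness_checks():
    """Closed-form checks of the cut-off and filtering rules."""
    h = np.arange(1.0, 101.0)
    return {
        "cutoff_1_to_100_at_95": float(candidate_cutoff(h, retain=0.95)),
        "cutoff_all_equal_7": float(candidate_cutoff(np.full(30, 7.0))),
    }


def sync_error_experiment(seed: int, n_tags: int = 16, days: float = 14.0):
    """HPEm percentiles of a synthetic sync-tag array at the default
    observation-error calibration."""
    raster = BenthoscapeRaster(0, 0, 10.0, np.full((100, 100), 4))
    cfg = SimulationConfig()
    sync = generate_sync_tags(raster, n_tags, cfg, duration=days * 86400.0, seed=seed)
    med, p90, p95 = np.percentile(sync["hpem"], [50, 90, 95])
    from scipy.stats import spearmanr

    rho = spearmanr(sync["hpe"], sync["hpem"]).statistic
    return {
        "hpem_median_m": float(med),
        "hpem_p90_m": float(p90),
        "hpem_p95_m": float(p95),
        "hpe_hpem_spearman": float(rho),
        "n_fixes": int(len(sync)),
    }


def kernel_recovery_experiment(seed: int, n: int = 100_000):
    """Gamma and von Mises MLE recovery at large n (relative errors)."""
    rng = np.random.default_rng(seed)
    g = fit_gamma(rng.gamma(2.0, 3.0, size=n))
    v = fit_vonmises(rng.vonmises(0.0, 4.0, size=n))
    return {
        "gamma_shape_rel_err": abs(g.shape - 2.0) / 2.0,
        "gamma_scale_rel_err": abs(g.scale - 3.0) / 3.0,
        "vonmises_kappa_rel_err": abs(v.kappa - 4.0) / 4.0,
        "n": n,
    }
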