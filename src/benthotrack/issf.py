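"""Integrated step-selection functions per individual.

Workflow (per individual): fit a *tentative* movement kernel — gamma to
observed step lengths, von Mises (mean 0) to observed turning angles —
then pair each observed step with random alternative steps drawn from
that kernel about the previous bearing. The matched sets (strata) feed a
conditional logistic regression with the model

    case ~ end substrate + log(sl) + cos(ta)
           + start substrate : log(sl) + start substrate : cos(ta)
           + strata

Start-substrate *main* effects are stratum-constant and hence
inestimable under the conditional likelihood; only their interactions
with the movement terms enter, which is also what the model formula
prescribes. Uncertainty comes from a stratum bootstrap (default 1000
replicates). The fitted log(sl) and cos(ta) coefficients update the
tentative kernel: on the reference substrate the gamma shape gains the
log(sl) coefficient and the von Mises concentration gains the cos(ta)
coefficient; on other substrates the respective start-class interaction
is added as well.

Sign conventions for interpretation: a negative start-class x cos(ta)
coefficient means lower directionality (more turning) on that substrate;
a negative start-class x log(sl) coefficient means shorter steps (more
resident behaviour); end-class coefficients are habitat selection
relative to the reference substrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import REFERENCE_CLASS, SUBSTRATE_NAMES, BenthoscapeRaster
from .stats.clogit import BootstrapResult, FitResult, bootstrap_clogit, fit_clogit
from .stats.distributions import MovementKernel, fit_gamma, fit_vonmises

N_RANDOM_STEPS: int = 100
N_BOOTSTRAP: int = 1000
MIN_STRATA: int = 20


def fit_tentative_kernel(steps: pd.DataFrame) -> MovementKernel:
    """Tentative movement kernel from one individual's observed steps."""
    usable = steps[np.isfinite(steps["log_sl"]) & steps["ta"].notna()]
    return MovementKernel(
        gamma=fit_gamma(usable["sl"].to_numpy(dtype=float)),
        vonmises=fit_vonmises(usable["ta"].to_numpy(dtype=float)),
    )


def draw_random_steps(
    steps: pd.DataFrame,
    kernel: MovementKernel,
    raster: BenthoscapeRaster,
    n_random: int = N_RANDOM_STEPS,
    seed: int | np.random.Generator = 0,
    retry_cap: int = 100,
) -> pd.DataFrame:
    """Stratified steps: each observed step plus ``n_random`` alternatives.

    Only observed steps with a computable turning angle and finite log
    step length form strata (random turning angles are drawn about the
    previous bearing, which the first step of a burst does not have).
    Random endpoints beyond the raster extent are redrawn up to
    ``retry_cap`` rounds, after which the stratum is dropped with a
    warning; endpoints on unmapped cells keep the NODATA class.

    Returns a long table with columns stratum, case, sl, log_sl, ta,
    cos_ta, start_class, end_class.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = steps[np.isfinite(steps["log_sl"]) & steps["ta"].notna()].reset_index(drop=True)
    if obs.empty:
        raise ValueError("no observed steps with computable turning angles")
    n_strata = len(obs)
    xmin, ymin, xmax, ymax = raster.bounds
    # previous bearing = bearing of the observed step minus its turning angle
    bearing = np.arctan2(
        obs["y_end"].to_numpy() - obs["y_start"].to_numpy(),
        obs["x_end"].to_numpy() - obs["x_start"].to_numpy(),
    )
    prev_bearing = bearing - obs["ta"].to_numpy(dtype=float)

    sl = rng.gamma(kernel.gamma.shape, kernel.gamma.scale, size=(n_strata, n_random))
    if kernel.vonmises.kappa > 0:
        ta = rng.vonmises(0.0, kernel.vonmises.kappa, size=(n_strata, n_random))
    else:
        ta = rng.uniform(-np.pi, np.pi, size=(n_strata, n_random))
    direction = prev_bearing[:, None] + ta
    ex = obs["x_start"].to_numpy()[:, None] + sl * np.cos(direction)
    ey = obs["y_start"].to_numpy()[:, None] + sl * np.sin(direction)
    oob = ~((ex >= xmin) & (ex < xmax) & (ey >= ymin) & (ey < ymax))
    for _ in range(retry_cap):
        if not oob.any():
            break
        k = int(oob.sum())
        idx = np.nonzero(oob)
        new_sl = rng.gamma(kernel.gamma.shape, kernel.gamma.scale, size=k)
        new_ta = (
            rng.vonmises(0.0, kernel.vonmises.kappa, size=k)
            if kernel.vonmises.kappa > 0
            else rng.uniform(-np.pi, np.pi, size=k)
        )
        nd = prev_bearing[idx[0]] + new_ta
        nx = obs["x_start"].to_numpy()[idx[0]] + new_sl * np.cos(nd)
        ny = obs["y_start"].to_numpy()[idx[0]] + new_sl * np.sin(nd)
        ok = (nx >= xmin) & (nx < xmax) & (ny >= ymin) & (ny < ymax)
        sl[idx[0][ok], idx[1][ok]] = new_sl[ok]
        ta[idx[0][ok], idx[1][ok]] = new_ta[ok]
        ex[idx[0][ok], idx[1][ok]] = nx[ok]
        ey[idx[0][ok], idx[1][ok]] = ny[ok]
        oob[idx[0][ok], idx[1][ok]] = False
    bad_strata = oob.any(axis=1)
    if bad_strata.any():
        warnings.warn(
            f"dropping {int(bad_strata.sum())} strata whose random steps "
            "could not be kept inside the raster extent",
            stacklevel=2,
        )
    keep = ~bad_strata
    obs = obs[keep].reset_index(drop=True)
    sl, ta, ex, ey = sl[keep], ta[keep], ex[keep], ey[keep]
    n_strata = len(obs)
    end_class = raster.extract_code(ex.ravel(), ey.ravel()).reshape(ex.shape)

    frames = [
        pd.DataFrame(
            {
                "stratum": np.arange(n_strata),
                "case": True,
                "sl": obs["sl"].to_numpy(dtype=float),
                "log_sl": obs["log_sl"].to_numpy(dtype=float),
                "ta": obs["ta"].to_numpy(dtype=float),
                "cos_ta": obs["cos_ta"].to_numpy(dtype=float),
                "start_class": obs["start_class"].to_numpy(),
                "end_class": obs["end_class"].to_numpy(),
            }
        ),
        pd.DataFrame(
            {
                "stratum": np.repeat(np.arange(n_strata), n_random),
                "case": False,
                "sl": sl.ravel(),
                "log_sl": np.log(sl.ravel()),
                "ta": ta.ravel(),
                "cos_ta": np.cos(ta.ravel()),
                "start_class": np.repeat(obs["start_class"].to_numpy(), n_random),
                "end_class": end_class.ravel(),
            }
        ),
    ]
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["stratum", "case"], ascending=[True, False]).reset_index(drop=True)


def build_issf_design(
    strata: pd.DataFrame,
    reference: int = REFERENCE_CLASS,
    min_support: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Design matrix for the conditional fit.

    Columns: end-substrate dummies (reference-coded over levels present
    in ``end_class``), log_sl, cos_ta, then start-substrate interactions
    with log_sl and cos_ta for each non-reference start level present.
    Returns (X, y, stratum ids, term names).

    ``min_support`` (when > 0) excludes the end dummy of any level the
    observed animal ended on fewer than that many times, and the start
    interactions of any level with fewer than that many strata starting
    there. An individual that barely touched a substrate cannot identify
    its coefficient — such levels produce separation-scale estimates
    under resampling — so their terms are omitted for that individual,
    the per-individual analogue of a substrate the animal never used.
    """
    cases_ = strata[strata["case"]]
    end_counts = cases_["end_class"].value_counts()
    start_counts = cases_["start_class"].value_counts()
    end_levels = sorted(
        lev for lev in set(strata["end_class"]) - {reference}
        if int(end_counts.get(lev, 0)) >= min_support
    )
    start_levels = sorted(
        lev for lev in set(strata["start_class"]) - {reference}
        if int(start_counts.get(lev, 0)) >= min_support
    )
    cols = []
    terms = []
    end = strata["end_class"].to_numpy()
    start = strata["start_class"].to_numpy()
    for lev in end_levels:
        cols.append((end == lev).astype(float))
        terms.append(f"end_{lev}")
    cols.append(strata["log_sl"].to_numpy(dtype=float))
    terms.append("log_sl")
    cols.append(strata["cos_ta"].to_numpy(dtype=float))
    terms.append("cos_ta")
    for lev in start_levels:
        cols.append((start == lev) * strata["log_sl"].to_numpy(dtype=float))
        terms.append(f"start_{lev}:log_sl")
    for lev in start_levels:
        cols.append((start == lev) * strata["cos_ta"].to_numpy(dtype=float))
        terms.append(f"start_{lev}:cos_ta")
    X = np.column_stack(cols)
    y = strata["case"].to_numpy(dtype=float)
    return X, y, strata["stratum"].to_numpy(), terms


@dataclass
class ISSFEstimates:
    """Per-individual iSSF fit: point estimates plus bootstrap summary."""

    tag_id: str
    fit: FitResult
    bootstrap: BootstrapResult
    n_strata: int

    def table(self) -> pd.DataFrame:
        """Term-by-term table: estimate, SE, bootstrap mean/SD, CIs."""
        lo_w = hi_w = None
        if self.fit.se is not None:
            lo_w = self.fit.beta - 1.96 * self.fit.se
            hi_w = self.fit.beta + 1.96 * self.fit.se
        lo_p, hi_p = self.bootstrap.percentile_interval(0.95)
        return pd.DataFrame(
            {
                "term": self.fit.terms,
                "estimate": self.fit.beta,
                "se": self.fit.se if self.fit.se is not None else np.nan,
                "boot_mean": self.bootstrap.mean,
                "boot_sd": self.bootstrap.sd,
                "wald_lo": lo_w,
                "wald_hi": hi_w,
                "pct_lo": lo_p,
                "pct_hi": hi_p,
            }
        ).set_index("term")


def fit_issf(
    strata: pd.DataFrame,
    B: int = N_BOOTSTRAP,
    seed: int = 0,
    reference: int = REFERENCE_CLASS,
    min_strata: int = MIN_STRATA,
    min_support: int = 5,
    tag_id: str = "",
) -> ISSFEstimates:
    """Conditional fit plus stratum bootstrap for one individual.

    Refuses individuals with fewer than ``min_strata`` strata (too little
    data for a stable per-individual fit, mirroring the exclusion of
    sparsely tracked animals). Substrate levels with fewer than
    ``min_support`` observed uses contribute no term (see
    :func:`build_issf_design`).
    """
    n_strata = strata["stratum"].nunique()
    if n_strata < min_strata:
        raise ValueError(
            f"{n_strata} strata < required minimum {min_strata}: "
            "not enough positions for a per-individual iSSF"
        )
    X, y, sid, terms = build_issf_design(
        strata, reference=reference, min_support=min_support
    )
    fit = fit_clogit(X, y, sid, terms=terms)
    boot = bootstrap_clogit(X, y, sid, B=B, seed=seed, terms=terms)
    return ISSFEstimates(tag_id=tag_id, fit=fit, bootstrap=boot, n_strata=n_strata)


def update_kernel(
    tentative: MovementKernel,
    estimates: pd.DataFrame,
    reference: int = REFERENCE_CLASS,
    column: str = "estimate",
) -> pd.DataFrame:
    """Movement kernel per start substrate after selection correction.

    On the reference substrate, shape* = tentative shape + beta(log_sl)
    and kappa* = tentative kappa + beta(cos_ta); every other substrate
    adds its start-class interaction coefficient on top. Non-positive
    corrected shapes or negative concentrations are flagged invalid
    rather than raised.
    """
    est = estimates[column]
    b_logsl = float(est.get("log_sl", 0.0))
    b_costa = float(est.get("cos_ta", 0.0))
    classes = sorted(
        {reference}
        | {
            int(t.split("_")[1].split(":")[0])
            for t in estimates.index
            if t.startswith("start_")
        }
    )
    rows = []
    for c in classes:
        add_sl = float(est.get(f"start_{c}:log_sl", 0.0)) if c != reference else 0.0
        add_ct = float(est.get(f"start_{c}:cos_ta", 0.0)) if c != reference else 0.0
        shape = tentative.gamma.shape + b_logsl + add_sl
        kappa = tentative.vonmises.kappa + b_costa + add_ct
        rows.append(
            {
                "substrate": c,
                "name": SUBSTRATE_NAMES.get(c, str(c)),
                "shape": shape,
                "scale": tentative.gamma.scale,
                "kappa": kappa,
                "valid": bool(shape > 0 and kappa >= 0),
            }
        )
    return pd.DataFrame(rows).set_index("substrate")


def interpret_estimates(
    estimates: pd.DataFrame, column: str = "boot_mean"
) -> pd.DataFrame:
    """Sign-based behavioural reading of the fitted terms.

    A pure function of coefficient signs: negative start x cos(ta) means
    lower directionality (more turning) on that substrate; negative
    start x log(sl) means shorter steps (more resident behaviour);
    end-substrate coefficients translate to selection for (RSS > 1) or
    avoidance of (RSS < 1) that substrate relative to the reference.
    """
    rows = []
    for term in estimates.index:
        v = float(estimates.loc[term, column])
        if term.startswith("end_"):
            c = int(term.split("_")[1])
            if v > 0:
                label = "selected over reference"
            elif v < 0:
                label = "avoided relative to reference"
            else:
                label = "no difference from reference"
            kind = "habitat selection"
        elif term.endswith(":cos_ta"):
            c = int(term.split("_")[1].split(":")[0])
            if v < 0:
                label = "lower directionality / more turning"
            elif v > 0:
                label = "higher directionality"
            else:
                label = "no difference from reference"
            kind = "directionality"
        elif term.endswith(":log_sl"):
            c = int(term.split("_")[1].split(":")[0])
            if v < 0:
                label = "shorter steps / more resident"
            elif v > 0:
                label = "longer steps / more exploratory"
            else:
                label = "no difference from reference"
            kind = "step length"
        else:
            continue  # bare log_sl / cos_ta are kernel corrections
        rows.append(
            {
                "term": term,
                "substrate": c,
                "name": SUBSTRATE_NAMES.get(c, str(c)),
                "kind": kind,
                "value": v,
                "interpretation": label,
            }
        )
    return pd.DataFrame(rows).set_index("term")
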