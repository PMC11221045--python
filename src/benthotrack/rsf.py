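"""Resource selection functions with the subsample-refit scheme.

The use-available design contrasts observed presences with pseudo-absences
drawn uniformly from each individual's availability domain (default: the
minimum convex polygon of its presences), at 10 pseudo-absences per
presence. Presence vs pseudo-absence is modelled by logistic regression on
substrate class with a random intercept per individual. To blunt spatial
autocorrelation, the model is rerun 100 times on random subsets of 100
presence and 100 pseudo-absence points per individual; exponentiating
each rerun's class coefficients yields a distribution of relative
selection strengths (RSS) per substrate against the baseline class.

Notes on conventions: the "100 presence and pseudo-absence points per
individual" subsets are read as 100 of each (equal-count); in the
use-available logistic framework the use:available ratio moves only the
intercept, not the class coefficients. The alternative reading (100
presences plus all their paired absences) is available via
``subset_mode="paired"``. Pseudo-absences are drawn once and subsampled
per rerun.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

from .raster import REFERENCE_CLASS, BenthoscapeRaster
from .stats.clogit import SeparationError
from .stats.logistic import fit_logistic_re

logger = logging.getLogger(__name__)

PSEUDO_ABSENCE_RATIO: int = 10
N_RERUNS: int = 100
PER_INDIVIDUAL: int = 100


def minimum_convex_polygon(x, y):
    """Convex hull of an individual's presence points (its MCP)."""
    hull = MultiPoint(np.column_stack([x, y])).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise ValueError(
            "presences are collinear or degenerate: the minimum convex "
            "polygon has zero area"
        )
    return hull


def draw_pseudo_absences(
    presences: pd.DataFrame,
    raster: BenthoscapeRaster,
    ratio: int = PSEUDO_ABSENCE_RATIO,
    domain=None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Use-available table for one individual.

    Draws ``ratio`` pseudo-absences per presence uniformly inside the
    availability domain (the presence MCP unless ``domain`` is given) and
    attaches substrate classes from the raster; points on unmapped cells
    keep the NODATA level. Returns rows of
    (tag_id, x, y, class, case) with ``case=True`` for presences.
    """
    if len(presences) < 5:
        raise ValueError(f"need at least 5 presences, got {len(presences)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tag = presences["tag_id"].iloc[0]
    px = presences["x_m"].to_numpy(dtype=float)
    py = presences["y_m"].to_numpy(dtype=float)
    poly = domain if domain is not None else minimum_convex_polygon(px, py)
    n_target = ratio * len(presences)
    xmin, ymin, xmax, ymax = poly.bounds
    ax = np.empty(0)
    ay = np.empty(0)
    # rejection sampling from the bounding box
    for _ in range(1000):
        need = n_target - ax.size
        if need <= 0:
            break
        batch = max(4 * need, 256)
        cx = rng.uniform(xmin, xmax, size=batch)
        cy = rng.uniform(ymin, ymax, size=batch)
        ok = shapely.contains_xy(poly, cx, cy)
        ax = np.concatenate([ax, cx[ok]])
        ay = np.concatenate([ay, cy[ok]])
    ax, ay = ax[:n_target], ay[:n_target]
    pres = pd.DataFrame(
        {"tag_id": tag, "x": px, "y": py,
         "substrate": raster.extract_code(px, py), "case": True}
    )
    absent = pd.DataFrame(
        {"tag_id": tag, "x": ax, "y": ay,
         "substrate": raster.extract_code(ax, ay), "case": False}
    )
    return pd.concat([pres, absent], ignore_index=True)


def build_use_available(
    fixes: pd.DataFrame,
    raster: BenthoscapeRaster,
    ratio: int = PSEUDO_ABSENCE_RATIO,
    seed: int = 0,
) -> pd.DataFrame:
    """Use-available table for all individuals in a filtered fix table."""
    ss = np.random.SeedSequence(seed)
    tags = sorted(fixes["tag_id"].unique())
    children = ss.spawn(len(tags))
    frames = []
    for tag, child in zip(tags, children):
        pres = fixes[fixes["tag_id"] == tag]
        try:
            frames.append(
                draw_pseudo_absences(
                    pres, raster, ratio=ratio, seed=np.random.default_rng(child)
                )
            )
        except ValueError as exc:
            warnings.warn(f"excluding {tag!r} from RSF: {exc}", stacklevel=2)
    if not frames:
        raise ValueError("no individual had enough presences for an RSF")
    return pd.concat(frames, ignore_index=True)


def _design(sub: pd.DataFrame, levels: list[int], reference: int):
    """Intercept + dummies for each non-reference class level."""
    cls = sub["substrate"].to_numpy()
    cols = [np.ones(len(sub))]
    terms = ["(Intercept)"]
    for lev in levels:
        if lev == reference:
            continue
        cols.append((cls == lev).astype(float))
        terms.append(f"substrate_{lev}")
    return np.column_stack(cols), terms


def rsf_resample_fit(
    data: pd.DataFrame,
    reruns: int = N_RERUNS,
    per_individual: int = PER_INDIVIDUAL,
    seed: int = 0,
    reference: int = REFERENCE_CLASS,
    subset_mode: str = "equal",
    ratio: int = PSEUDO_ABSENCE_RATIO,
) -> pd.DataFrame:
    """Rerun the RSF on random subsets, returning one coefficient row per rerun.

    Each rerun samples, per individual, ``per_individual`` presences and
    (equal-count mode) ``per_individual`` pseudo-absences without
    replacement, then fits presence ~ substrate with a random intercept
    per individual. ``subset_mode="paired"`` instead keeps
    ``ratio * per_individual`` absences per individual. Individuals with
    too few points are excluded with a logged warning.
    """
    if subset_mode not in {"equal", "paired"}:
        raise ValueError(f"unknown subset_mode {subset_mode!r}")
    n_abs = per_individual if subset_mode == "equal" else ratio * per_individual
    rng = np.random.default_rng(seed)
    usable = []
    for tag, grp in data.groupby("tag_id", sort=True):
        n_pres = int(grp["case"].sum())
        n_ab = int((~grp["case"]).sum())
        if n_pres >= per_individual and n_ab >= n_abs:
            usable.append(tag)
        else:
            logger.warning(
                "excluding %r from RSF reruns: %d presences / %d absences "
                "(need %d / %d)", tag, n_pres, n_ab, per_individual, n_abs,
            )
    if len(usable) < 2:
        raise ValueError(
            f"only {len(usable)} individual(s) have enough points for the "
            "subsample-refit scheme; need at least 2"
        )
    data = data[data["tag_id"].isin(usable)]
    levels = sorted(data["substrate"].unique())
    all_terms = ["(Intercept)"] + [f"substrate_{lev}" for lev in levels if lev != reference]
    rows = []
    n_separated = 0
    for r in range(reruns):
        parts = []
        for tag in usable:
            grp = data[data["tag_id"] == tag]
            pres = grp[grp["case"]]
            absent = grp[~grp["case"]]
            parts.append(pres.iloc[rng.choice(len(pres), per_individual, replace=False)])
            parts.append(absent.iloc[rng.choice(len(absent), n_abs, replace=False)])
        sub = pd.concat(parts, ignore_index=True)
        # a level whose subset rows are all one outcome has an infinite
        # MLE in this rerun: inestimable, recorded as NaN
        by_level = sub.groupby("substrate")["case"].agg(["sum", "size"])
        estimable = [
            lev for lev in levels
            if lev in by_level.index
            and 0 < by_level.loc[lev, "sum"] < by_level.loc[lev, "size"]
        ]
        X, terms = _design(sub[sub["substrate"].isin(estimable)], estimable, reference)
        keep = sub["substrate"].isin(estimable)
        try:
            fit, _sigma2 = fit_logistic_re(
                sub.loc[keep, "case"].to_numpy(dtype=float),
                X,
                sub.loc[keep, "tag_id"].to_numpy(),
                terms=terms,
            )
            row = dict(zip(terms, fit.beta))
        except SeparationError:
            n_separated += 1
            row = {}
        rows.append({t: row.get(t, np.nan) for t in all_terms} | {"rerun": r})
    if n_separated > reruns // 2:
        raise RuntimeError(
            f"{n_separated}/{reruns} reruns separated: the use-available "
            "data cannot support the subsample-refit scheme"
        )
    out = pd.DataFrame(rows).set_index("rerun")
    return out


def relative_selection_strength(
    coefficients: pd.DataFrame, reference: int = REFERENCE_CLASS
) -> pd.DataFrame:
    """Summarize rerun coefficients as relative selection strengths.

    Exponentiates each substrate coefficient and reports the median and
    interquartile range per class; a class whose IQR spans 1 shows both
    reduced and increased odds across reruns and is flagged as showing no
    clear selection. The reference class has RSS identically 1. Reruns
    where a class was inestimable (NaN) are excluded from its summary,
    with the estimable count reported.
    """
    if coefficients.empty:
        raise ValueError("no coefficient vectors supplied")
    rows = []
    cls_cols = [c for c in coefficients.columns if c.startswith("substrate_")]
    for col in cls_cols:
        rss = np.exp(coefficients[col].to_numpy(dtype=float))
        n_est = int(np.isfinite(rss).sum())
        if n_est == 0:
            q25 = med = q75 = np.nan
        else:
            q25, med, q75 = np.nanpercentile(rss, [25, 50, 75])
        rows.append(
            {
                "substrate": int(col.split("_")[1]),
                "rss_median": med,
                "rss_q25": q25,
                "rss_q75": q75,
                "no_clear_selection": bool(n_est == 0 or q25 < 1.0 < q75),
                "n_estimable": n_est,
            }
        )
    rows.append(
        {
            "substrate": reference,
            "rss_median": 1.0,
            "rss_q25": 1.0,
            "rss_q75": 1.0,
            "no_clear_selection": False,
            "n_estimable": len(coefficients),
        }
    )
    return pd.DataFrame(rows).set_index("substrate").sort_index()
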