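"""Regularize filtered fixes into bursts and build steps.

Irregular fix times (transmissions every 120-240 s, imperfect detection)
are thinned to an approximately constant sampling rate (default 10 min)
by a greedy rule: keep the first fix, then from each kept fix keep the
earliest subsequent fix whose gap falls within ``rate +/- tolerance``;
when the gap grows beyond ``rate + tolerance`` with no acceptable fix,
the burst is closed and a new one starts. Bursts of fewer than two kept
fixes carry no movement information and are dropped.

A step is the straight line between consecutive kept fixes. Turning
angles are the wrapped change in bearing between consecutive steps
(counter-clockwise positive, in (-pi, pi]); the first step of each burst
has no predecessor and therefore no turning angle. Steps with zero
length (infinite log step length) and steps without a computable turning
angle are removed before model fitting. Substrate is sampled at step
endpoints only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import BenthoscapeRaster

RATE_S: float = 600.0
TOLERANCE_S: float = 120.0

STEP_COLUMNS = [
    "tag_id", "burst_id", "t_start", "t_end",
    "x_start", "y_start", "x_end", "y_end",
    "sl", "log_sl", "ta", "cos_ta",
]


def wrap_angle(theta):
    """Wrap angle(s) into (-pi, pi]."""
    w = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w)


def clip_to_raster(fixes: pd.DataFrame, raster: BenthoscapeRaster) -> pd.DataFrame:
    """Drop fixes outside the raster extent.

    Positioning error can place a fix beyond the mapped area even when
    the animal stayed inside; analyses are restricted to positions
    within the benthoscape extent before steps are built.
    """
    xmin, ymin, xmax, ymax = raster.bounds
    x = fixes["x_m"].to_numpy(dtype=float)
    y = fixes["y_m"].to_numpy(dtype=float)
    ok = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
    return fixes[ok].reset_index(drop=True)


def resample(
    fixes: pd.DataFrame,
    rate: float = RATE_S,
    tolerance: float = TOLERANCE_S,
) -> pd.DataFrame:
    """Thin one tag's fixes to ~``rate`` seconds, splitting into bursts.

    Returns the kept fixes with a ``burst_id`` column. Input must be
    time-sorted; unsorted input is an error rather than silently fixed.
    """
    if fixes["tag_id"].nunique() > 1:
        raise ValueError("resample operates on one tag at a time")
    t = pd.to_datetime(fixes["t"]).astype("int64").to_numpy() / 1e9
    if np.any(np.diff(t) < 0):
        raise ValueError("fixes must be sorted by time")
    lo, hi = rate - tolerance, rate + tolerance
    kept_idx: list[int] = []
    burst_ids: list[int] = []
    burst = 0
    i = 0
    n = len(t)
    while i < n:
        # start a burst at fix i
        start_of_burst = len(kept_idx)
        kept_idx.append(i)
        burst_ids.append(burst)
        cur = i
        j = cur + 1
        while j < n:
            gap = t[j] - t[cur]
            if gap < lo:
                j += 1
            elif gap <= hi:
                kept_idx.append(j)
                burst_ids.append(burst)
                cur = j
                j += 1
            else:
                break
        # burst closed: next burst starts at the first fix after `cur`
        # that was not reachable (j, which exceeded the window), or ends
        if len(kept_idx) - start_of_burst < 2:
            # singleton burst: discard it
            del kept_idx[start_of_burst:]
            del burst_ids[start_of_burst:]
        else:
            burst += 1
        i = j
    out = fixes.iloc[kept_idx].copy()
    out["burst_id"] = burst_ids
    return out.reset_index(drop=True)


def build_steps(burst: pd.DataFrame) -> pd.DataFrame:
    """One step per consecutive fix pair of a single burst.

    The first step's turning angle is missing (NaN): there is no
    previous bearing to turn from.
    """
    if burst["burst_id"].nunique() > 1:
        raise ValueError("build_steps operates on one burst")
    if len(burst) < 2:
        return pd.DataFrame(columns=STEP_COLUMNS)
    x = burst["x_m"].to_numpy(dtype=float)
    y = burst["y_m"].to_numpy(dtype=float)
    t = pd.to_datetime(burst["t"]).to_numpy()
    dx = np.diff(x)
    dy = np.diff(y)
    sl = np.hypot(dx, dy)
    with np.errstate(divide="ignore"):
        log_sl = np.log(sl)
    bearing = np.arctan2(dy, dx)
    ta = np.full(sl.size, np.nan)
    if sl.size > 1:
        ta[1:] = wrap_angle(bearing[1:] - bearing[:-1])
    return pd.DataFrame(
        {
            "tag_id": burst["tag_id"].iloc[0],
            "burst_id": burst["burst_id"].iloc[0],
            "t_start": t[:-1],
            "t_end": t[1:],
            "x_start": x[:-1],
            "y_start": y[:-1],
            "x_end": x[1:],
            "y_end": y[1:],
            "sl": sl,
            "log_sl": log_sl,
            "ta": ta,
            "cos_ta": np.cos(ta),
        }
    )


def steps_from_fixes(
    fixes: pd.DataFrame, rate: float = RATE_S, tolerance: float = TOLERANCE_S
) -> pd.DataFrame:
    """Resample and build steps for every tag in a fix table."""
    frames = []
    for tag, grp in fixes.groupby("tag_id", sort=True):
        kept = resample(grp.sort_values("t").reset_index(drop=True), rate, tolerance)
        for _, b in kept.groupby("burst_id", sort=True):
            frames.append(build_steps(b))
    if not frames:
        return pd.DataFrame(columns=STEP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def filter_steps(steps: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop steps unusable for model fitting, with per-reason counts.

    Removes steps with non-finite log step length (zero-length moves)
    and steps whose turning angle is missing (first step of a burst).
    """
    if steps.empty:
        return steps.copy(), {"infinite_log_sl": 0, "missing_ta": 0}
    bad_sl = ~np.isfinite(steps["log_sl"].to_numpy(dtype=float))
    bad_ta = steps["ta"].isna().to_numpy() & ~bad_sl
    kept = steps[~(bad_sl | steps["ta"].isna().to_numpy())].reset_index(drop=True)
    return kept, {"infinite_log_sl": int(bad_sl.sum()), "missing_ta": int(bad_ta.sum())}


def attach_covariates(steps: pd.DataFrame, raster: BenthoscapeRaster) -> pd.DataFrame:
    """Attach substrate class at the start and end of each step.

    Endpoints on cells without substrate data keep the NODATA level (it
    is an ordinary category downstream); endpoints beyond the raster
    extent raise.
    """
    out = steps.copy()
    if out.empty:
        out["start_class"] = pd.Series(dtype=np.int64)
        out["end_class"] = pd.Series(dtype=np.int64)
        return out
    out["start_class"] = raster.extract_code(
        out["x_start"].to_numpy(), out["y_start"].to_numpy()
    )
    out["end_class"] = raster.extract_code(
        out["x_end"].to_numpy(), out["y_end"].to_numpy()
    )
    return out
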