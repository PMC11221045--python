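"""Positioning quality control for fine-scale acoustic telemetry.

Implements the filtering protocol used with error-calibrated positioning
arrays: per-deployment HPE cut-off candidates are the lowest observed HPE
retaining 95% of sync-tag positions; filtered sync fixes are summarized
by the median / 90th / 95th percentiles of the measured error HPEm; and
animal fixes are kept only when their HPE is strictly below the chosen
final cut-off and they fall at least 48 h after the individual's release
(to exclude post-handling behaviour).

Candidate selection uses ``<=`` (a retention definition); the final
animal filter uses strict ``<`` (the convention in which the chosen
cut-off is quoted, e.g. "HPE < 25"). The final cut-off itself is a
configuration choice, not an algorithm: the protocol produces
per-deployment candidates and reports and a human balances retention
against confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POST_RELEASE_HOURS: float = 48.0
DEFAULT_RETAIN: float = 0.95
#: The final HPE cut-off used for animal fixes (strict <).
DEFAULT_CUTOFF: float = 25.0


@dataclass(frozen=True)
class CutoffReport:
    """Retention and HPEm summary of sync fixes at a given HPE cut-off."""

    cutoff: float
    retention: float
    hpem_median: float
    hpem_p90: float
    hpem_p95: float
    n_total: int
    n_retained: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.retention <= 1.0):
            raise ValueError("retention must be in [0, 1]")
        if not (self.hpem_median <= self.hpem_p90 <= self.hpem_p95):
            raise ValueError("HPEm percentiles must be non-decreasing")


def candidate_cutoff(hpe, retain: float = DEFAULT_RETAIN) -> float:
    """Smallest observed HPE value retaining at least ``retain`` of fixes.

    ``h*`` is minimal over *observed* values: any strictly smaller
    observed HPE keeps a fraction < ``retain``.
    """
    h = np.asarray(hpe, dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        raise ValueError("no HPE values supplied")
    if not (0.0 < retain <= 1.0):
        raise ValueError("retain must be in (0, 1]")
    s = np.sort(h)
    k = int(np.ceil(retain * s.size))
    return float(s[k - 1])


def deployment_cutoffs(
    sync_fixes: pd.DataFrame, retain: float = DEFAULT_RETAIN, min_fixes: int = 20
) -> dict[str, float]:
    """Per-deployment candidate cut-offs from sync-tag fixes.

    Each array deployment is treated as its own dataset.
    """
    sync = sync_fixes[sync_fixes["is_sync"]]
    out: dict[str, float] = {}
    for dep, grp in sync.groupby("deployment_id"):
        if len(grp) < min_fixes:
            raise ValueError(
                f"deployment {dep!r} has only {len(grp)} sync fixes (< {min_fixes})"
            )
        out[str(dep)] = candidate_cutoff(grp["hpe"].to_numpy(), retain=retain)
    if not out:
        raise ValueError("no sync fixes supplied")
    return out


def cutoff_report(sync_fixes: pd.DataFrame, cutoff: float) -> CutoffReport:
    """HPEm percentile report for sync fixes passing ``hpe <= cutoff``.

    Percentiles use linear interpolation between order statistics.
    """
    if not cutoff > 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    sync = sync_fixes[sync_fixes["is_sync"]]
    hpe = sync["hpe"].to_numpy(dtype=float)
    hpem = sync["hpem"].to_numpy(dtype=float)
    passing = hpe <= cutoff
    if not passing.any():
        raise ValueError(f"no sync fixes pass HPE <= {cutoff}")
    kept = hpem[passing]
    med, p90, p95 = np.percentile(kept, [50, 90, 95])
    return CutoffReport(
        cutoff=float(cutoff),
        retention=float(passing.mean()),
        hpem_median=float(med),
        hpem_p90=float(p90),
        hpem_p95=float(p95),
        n_total=int(hpe.size),
        n_retained=int(passing.sum()),
    )


def filter_positions(
    fixes: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    releases: dict[str, pd.Timestamp] | None = None,
    post_release_hours: float = POST_RELEASE_HOURS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter animal fixes by HPE and the post-release window.

    Keeps animal fixes with ``hpe`` strictly below ``cutoff`` and
    timestamp at least ``post_release_hours`` after the tag's release.
    Release times come from ``releases`` (tag -> timestamp) or, if not
    given, from the ``release_t`` column. Sync fixes are dropped (they
    are calibration, not animal data).

    Returns
    -------
    (filtered fixes, per-tag counts) — counts has columns
    ``n_before, n_after_hpe, n_after`` indexed by tag.
    """
    animals = fixes[~fixes["is_sync"]].copy()
    tags = animals["tag_id"].unique()
    if releases is not None:
        unknown = [t for t in tags if t not in releases]
        if unknown:
            raise KeyError(f"no release time for tag(s): {unknown}")
        rel = animals["tag_id"].map(releases)
    else:
        if animals["release_t"].isna().any():
            bad = animals.loc[animals["release_t"].isna(), "tag_id"].unique().tolist()
            raise KeyError(f"missing release time for tag(s): {bad}")
        rel = animals["release_t"]
    rel = pd.to_datetime(rel)
    keep_hpe = animals["hpe"] < cutoff
    keep_t = animals["t"] >= rel + pd.to_timedelta(post_release_hours, unit="h")
    kept = animals[keep_hpe & keep_t]
    counts = pd.DataFrame(
        {
            "n_before": animals.groupby("tag_id").size(),
            "n_after_hpe": animals[keep_hpe].groupby("tag_id").size(),
            "n_after": kept.groupby("tag_id").size(),
        }
    ).fillna(0).astype(int)
    return kept.reset_index(drop=True), counts
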