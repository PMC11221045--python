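#!/usr/bin/env python
"""Regularize the filtered fixes into 10-minute bursts and build steps.

Fixes are thinned to a ~600-s sampling rate (tolerance 120 s), split
into bursts wherever the gap cannot be bridged, and consecutive kept
fixes become steps with length, log length, turning angle and substrate
class at both endpoints.

Reads results/pipeline/positions_filtered.csv + benthoscape.asc; writes
steps.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

from analysis_config import CONFIG, OUT

from benthotrack import trackprep
from benthotrack.pipeline import _Manifest, stage_prep
from benthotrack.raster import read_raster


def main() -> None:
    filtered = pd.read_csv(
        OUT / "positions_filtered.csv", parse_dates=["t", "release_t"]
    )
    raster = read_raster(OUT / "benthoscape.asc")
    manifest = _Manifest(OUT)
    steps = stage_prep(CONFIG, filtered, raster, OUT, manifest)
    manifest.write()
    per_tag = steps.groupby("tag_id").size()
    print(f"built {len(steps)} steps in "
          f"{steps.groupby(['tag_id', 'burst_id']).ngroups} bursts")
    print(per_tag.to_string())
    usable = steps[np.isfinite(steps["log_sl"]) & steps["ta"].notna()]
    print(f"{len(usable)} steps have finite log step length and a "
          "computable turning angle (usable for the step-selection fit)")
    print(f"median step length: {steps['sl'].median():.1f} m per 10 min")


if __name__ == "__main__":
    main()
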