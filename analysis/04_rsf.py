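#!/usr/bin/env python
"""Resource selection: pseudo-absences, subsample-refit, RSS summary.

Each individual's presences are contrasted against 10 pseudo-absences
per presence drawn from its minimum convex polygon; presence ~ substrate
is fitted with a random intercept per individual, rerun 100 times on
100-point-per-individual subsets; exponentiated coefficients give the
relative selection strength (RSS) distribution per substrate against the
reference class (silt/mud with <= 50% gravel).

Reads results/pipeline/positions_filtered.csv + benthoscape.asc; writes
rsf_coefficients.csv, rsf_rss.json, report_rss_boxplot.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

from analysis_config import CONFIG, OUT, TRUE_BETA

from benthotrack.pipeline import _Manifest, stage_rsf, write_reports
from benthotrack.raster import SUBSTRATE_NAMES, read_raster


def main() -> None:
    filtered = pd.read_csv(
        OUT / "positions_filtered.csv", parse_dates=["t", "release_t"]
    )
    raster = read_raster(OUT / "benthoscape.asc")
    manifest = _Manifest(OUT)
    coefs, rss = stage_rsf(CONFIG, filtered, raster, OUT, manifest)
    write_reports(rss, {}, OUT, manifest)
    manifest.write()
    print(f"{len(coefs)} reruns of the subsample-refit scheme")
    print("median RSS per substrate (reference = "
          f"{SUBSTRATE_NAMES[1]!r}):")
    for cls, row in rss.iterrows():
        name = SUBSTRATE_NAMES.get(int(cls), str(cls))
        truth = float(np.exp(TRUE_BETA.get(int(cls), 0.0)))
        flag = "  [no clear selection]" if row["no_clear_selection"] else ""
        print(f"  {name:<40s} median {row['rss_median']:.2f} "
              f"(IQR {row['rss_q25']:.2f}-{row['rss_q75']:.2f}); "
              f"generating RSS {truth:.2f}{flag}")
    print("note: observed positions carry ~2.4 m positioning error, which "
          "attenuates contrasts toward 1 relative to the generating values")


if __name__ == "__main__":
    main()
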