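#!/usr/bin/env python
"""Compute NDTI from the SWIR raster and extract per-plot values.

NDTI = (SWIR1 − SWIR2) / (SWIR1 + SWIR2) per 30 m pixel, rescaled
affinely to 0–100 (no calibration), sampled at each plot's coordinate
(containing-pixel convention).  Output: results/pipeline/ndti.csv.
"""

from pathlib import Path

import pandas as pd

from rescover.pipeline import RunConfig, stage_ndti

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main() -> None:
    conf = RunConfig.from_json(OUT / "run_config.json")
    stage_ndti(conf, OUT)
    nd = pd.read_csv(OUT / "ndti.csv")
    print(f"extracted scaled NDTI for {len(nd)} plots "
          f"(range {nd['m6_value'].min():.1f}-{nd['m6_value'].max():.1f})")


if __name__ == "__main__":
    main()
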