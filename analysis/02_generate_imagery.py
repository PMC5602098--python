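#!/usr/bin/env python
"""Render the aerial stand-ins for the simulated survey.

For every plot in the drone subsample a straw-on-soil RGB scene is
rendered from a residue mask built to the plot's benchmark cover; the
whole sample is embedded in a two-band SWIR raster (30 m pixels) whose
tillage signal decreases SWIR2 with residue cover.  Scenes under
results/pipeline/images/, raster at results/pipeline/raster.tif.
"""

from pathlib import Path

from rescover.pipeline import RunConfig, stage_images, stage_raster

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main() -> None:
    conf = RunConfig.from_json(OUT / "run_config.json")
    stage_images(conf, OUT)
    stage_raster(conf, OUT)
    n = len(list((OUT / "images").glob("plot_????.png")))
    print(f"rendered {n} drone scenes (shape {conf.image_shape}, "
          f"contrast {conf.contrast}) and one {conf.raster_shape} SWIR raster")


if __name__ == "__main__":
    main()
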