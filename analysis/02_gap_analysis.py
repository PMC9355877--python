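#!/usr/bin/env python
"""Gap analysis of the synthetic FRC networks: mesh size from circle packing.

Binarizes each network image, packs maximal non-overlapping circles into the
free space, and compares the radius distributions of the two mesh sizes.
A stretched (doubled-spacing) network should show a clearly larger median
gap radius — the readout used to detect network stretching in inflamed
lymph nodes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from frcmech import core
from frcmech.gaps import binarize_network, fit_gap_circles, overlay_figure, radius_distribution

DATA = Path("results/data")
OUT = Path("results/gap_analysis")
OUT.mkdir(parents=True, exist_ok=True)
PIXEL_SIZE_UM = 0.5

summary = []
for spacing in (20, 40):
    stack = core.read_image(DATA / f"network_spacing{spacing}.tif", PIXEL_SIZE_UM)
    image = stack.planes[0]
    mask, prov = binarize_network(image)
    result = fit_gap_circles(mask, PIXEL_SIZE_UM, r_min_px=6.0, provenance=prov)
    core.write_table(result.circles, OUT / f"circles_spacing{spacing}.csv")
    overlay_figure(image, result, OUT / f"overlay_spacing{spacing}.png")
    dist = radius_distribution(result, threshold_um=0.0)
    summary.append({"spacing_px": spacing, "n_circles": dist["count"],
                    "median_radius_um": dist["median_um"], "iqr_um": dist["iqr_um"],
                    "otsu_threshold": prov["threshold"]})

df = pd.DataFrame(summary)
df.to_csv(OUT / "summary.csv", index=False)
ratio = df.median_radius_um.iloc[1] / df.median_radius_um.iloc[0]
print(df.to_string(index=False))
print(f"\nDoubling the mesh spacing raised the median gap radius "
      f"{ratio:.2f}x ({df.median_radius_um.iloc[0]:.1f} -> "
      f"{df.median_radius_um.iloc[1]:.1f} um): circle packing reads out mesh size.")
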