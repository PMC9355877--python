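#!/usr/bin/env python
"""Generate one synthetic dataset of every input class, with ground truth.

Writes network / nuclei images (TIFF), recoil landmark tracks, bead traces,
swelling traces and division-movie detections (CSV) under results/data/,
each next to a JSON or CSV ground-truth file.  These are the inputs the
later numbered scripts quantify.
"""

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from frcmech import core, synthetic as sx

OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1


def dump_truth(truth, path: Path) -> None:
    d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(truth).items()}
    path.write_text(json.dumps(d, indent=2, default=str))


# FRC-like network images at two mesh sizes (gap-analysis input)
for spacing in (20.0, 40.0):
    truth = sx.NetworkImageTruth(spacing_px=spacing, seed=SEED)
    image, free = sx.make_network_image(truth)
    core.write_image(image, OUT / f"network_spacing{int(spacing)}.tif")
    core.write_image(core.CalibratedImage2D(free.astype(np.uint8), truth.pixel_size_um),
                     OUT / f"network_spacing{int(spacing)}_free_mask.tif")
    dump_truth(truth, OUT / f"network_spacing{int(spacing)}_truth.json")

# nuclei field (packing-density input)
nuclei = sx.NucleiFieldTruth.random(30, seed=SEED)
core.write_image(sx.make_nuclei_image(nuclei), OUT / "nuclei.tif")
pd.DataFrame(nuclei.centroids, columns=["row", "col"]).to_csv(OUT / "nuclei_truth.csv", index=False)

# recoil landmark tracks, low- and high-tension arms
for arm, amp in (("low", 1.0), ("high", 2.0)):
    truth = sx.RecoilTruth(amplitude_A_um=amp, noise_sd_um=0.05, seed=SEED)
    times, a, b, cut = sx.make_landmark_tracks(truth)
    pd.DataFrame({"frame": np.arange(times.size), "t_s": times,
                  "x_a": a[:, 0], "y_a": a[:, 1],
                  "x_b": b[:, 0], "y_b": b[:, 1]}).to_csv(
        OUT / f"recoil_{arm}_tension.csv", index=False)
    dump_truth(truth, OUT / f"recoil_{arm}_tension_truth.json")

# trapped-bead trace with a tether-pull step
bead_truth = sx.BeadTraceTruth(tether_step_nm=100.0, step_time_s=600.0,
                               duration_s=900.0, seed=SEED)
track = sx.make_bead_trace(bead_truth)
pd.DataFrame({"t_s": track.times_s, "x_nm": track.position_nm}).to_csv(
    OUT / "bead.csv", index=False)
dump_truth(bead_truth, OUT / "bead_truth.json")

# swelling traces: isotonic control and hypotonic arm
rows = []
for cond, plat, rate in (("ISO", 1.0, 0.0), ("HYPO", 1.2, 0.2)):
    for i in range(10):
        truth = sx.SwellingTruth(plateau_ratio=plat, rate_per_min=rate,
                                 condition=cond, noise_sd_um=0.2, seed=SEED * 100 + i)
        trace = sx.make_swelling_trace(truth)
        for t, d in zip(trace.times_min, trace.diameter_um):
            rows.append({"cell": f"{cond}_{i}", "t_min": t, "diameter_um": d,
                         "condition": cond})
pd.DataFrame(rows).to_csv(OUT / "swelling_cells.csv", index=False)

# division movie detections (sparse, constraint-satisfying)
div_truth = sx.DivisionMovieTruth(n0=12, division_rate_per_cell_per_h=0.008,
                                  min_separation_px=60, motility_step_px=0.5, seed=SEED)
dets, events = sx.make_division_movie(div_truth)
dets.to_csv(OUT / "division_detections.csv", index=False)
core.write_table(events, OUT / "division_events_truth.csv")
dump_truth(div_truth, OUT / "division_truth.json")

print(f"wrote synthetic datasets to {OUT}/ ({len(events)} planted divisions, "
      f"{len(nuclei.centroids)} nuclei, 2 network mesh sizes)")
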