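# frcmech

Quantification toolkit for the mechanics of the lymph-node fibroblastic
reticular cell (FRC) network. FRCs form a contractile, interconnected
stromal scaffold in the T cell zone (paracortex); during an immune response
the network stretches, its tension changes, and the cells' membrane tension
and proliferation respond. This package implements the image- and
trace-based measurement procedures behind those readouts as a tested,
reusable library with a CLI — together with synthetic-data generators that
carry exact ground truth, so every stage can be verified end to end without
raw microscopy data.

## What it measures

| Stage | Readout | Core quantity |
|---|---|---|
| `gaps` | FRC-network mesh size | greedy maximal-circle packing of the binarized network's free space; radii reported strictly above a threshold (default 12 µm) |
| `packing` | T cell packing | nuclei per 100 µm² after despeckle, Gaussian blur (σ = 2 px), Otsu + watershed segmentation, and exclusion of nuclei inside the PDPN⁺ mask |
| `recoil` | Network tension (laser ablation) | v₀ = displacement one frame (0.521 s) after the cut ÷ frame interval; optional fit d(t) = A·(1 − e^(−t/τ)) |
| `tether` | Effective membrane tension | equipartition calibration k = k_B·T / Var(x); tether force F_T = kΔx |
| `swelling` | Membrane reservoir | diameter ratio d/d₀ every 30 s; ratio at 15 min; AUC of (ratio − 1) over the first 20 min |
| `fibers` | Actomyosin contractility | % pMLC⁺ and % matrix-aligned F-actin fibers among fibers inside the PDPN⁺ network |
| `divisions` | Stiffness-dependent proliferation | division events over 72 h normalized by the starting nucleus count |

The gap analysis is the geometric heart of the package: circles centered on
pixel centers are fitted consecutively, each the largest that contains no
network pixel, stays inside the image, and does not overlap a previously
fitted circle (center distance ≥ r_i + r_j, ties to the smallest (row, col)).
The implementation (Euclidean distance transform + incremental constraint
updates) is tested for *exact* equality — centers, radii, and order —
against an exhaustive brute-force oracle on hundreds of random masks.

## Worked example

Generate a synthetic FRC-like network and run the gap analysis:

```bash
frcmech simulate network --seed 3 --shape 96 96 --out sim
frcmech gap sim/network.tif --pixel-size-um 0.5 --threshold-um 12 --out gap_out
```

Or drive everything from Python. The numbered scripts under `analysis/`
run each stage on generated data (run `01_simulate_datasets.py` first);
`analysis/05_tether_force.py` prints:

```
trap stiffness k = 0.1147 pN/nm (truth 0.114, error 0.6%) from 6664 baseline samples
tether step dx = 99.9 nm (truth 100.0 nm)
tether force F = k*dx = 11.46 pN (truth 11.40 pN); flags: none
```

i.e. the equipartition calibration recovers the simulated trap stiffness
from the positional fluctuations of the trapped bead, the change-point
detector finds the tether-pull step, and F = kΔx returns the pulling force
in pN. Similarly `analysis/02_gap_analysis.py` reports that doubling the
synthetic mesh spacing raises the median fitted gap radius from 4.0 µm to
8.5 µm — the packing readout of network stretching — and
`analysis/08_divisions.py` shows divisions per cell rising monotonically
from soft (2 kPa) gels to glass.

Every CLI run writes a JSON manifest (resolved parameters, input hashes,
seed, package version) next to its outputs; repeated runs at a fixed seed
are byte-identical.

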