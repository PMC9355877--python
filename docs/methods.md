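# Methods

This note documents the models, conventions and numerical choices behind
each quantification stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the procedures were genuinely
open.

## Coordinate and unit conventions

Images are 0-based `(row, col)` pixel grids with pixel centers at integer
coordinates and an isotropic physical calibration (µm per pixel).
Anisotropic pixels are rejected rather than silently averaged. All physical
distances are Euclidean pixel distances × `pixel_size_um`; areas scale with
its square. Calibration comes from the caller/CLI, never from TIFF
metadata (dialects vary); a resolution tag, when present, is only logged.
Intensities are treated as relative: every threshold is data-derived (Otsu)
or explicitly configured.

## Gap analysis (mesh size by maximal-circle packing)

**Procedure.** The network image is lightly smoothed (Gaussian, σ = 0.5 px
by default) and binarized (Otsu by default; manual threshold and contrast
inversion available; a constant image degenerates to all-background with a
flag). Circles centered on pixel centers are then fitted greedily: at each
step the largest circle that (a) contains no foreground pixel, (b) lies
within the image bounds, and (c) does not overlap a previously fitted
circle. Fitting stops when the best feasible radius drops below `r_min_px`
(default 2). Reported distributions keep radii strictly greater than a
physical threshold (default 12 µm, matching how such distributions are
plotted for lymph-node tissue).

**Geometry.** A circle of radius r occupies the *open* disc (pixels at
distance < r). With this convention the maximal foreground-free radius at a
center equals its distance-transform value and is actually attained; under
a closed-disc rule the supremum is never attained, because a circle of
radius exactly equal to the obstacle distance would contain its nearest
obstacle pixel. Obstacles are the foreground pixels plus a virtual 1-px
border ring just outside the image, so circles never extend past the image
bounds (whether the historical tissue scripts clipped at borders is
unknown; this convention is declared, not inferred). Circle–circle overlap
is continuous geometry — circles overlap iff center distance < r_i + r_j,
touching allowed — rather than raster-based, which removes ambiguity at
tangency and lets an independent oracle reproduce the output bit for bit.
Ties among equal maximal radii break to the smallest (row, col).

**Implementation and oracle.** The implementation computes the obstacle
distance once (exact Euclidean distance transform of the padded free-space
mask) and maintains a per-pixel feasibility cap that each new circle lowers
via `min(cap, dist − r)`. The test oracle recomputes everything from
scratch each step with explicit pairwise distances and no distance
transform. Both reduce to the same real-valued expressions (square roots
of integers, subtraction of previously selected radii), so equality is
exact in floating point, and the acceptance suite asserts identical
centers, radii and order on 200 random masks up to 64×64.

**Reading mesh size.** The greedy packing saturates free space, so the
median over *all* circles is pinned just above `r_min` regardless of mesh
size — corner gaps between a mesh cell's inscribed circle and its fibers
always admit small infill circles. Mesh size is therefore read from the
distribution above a floor set by the expected mesh scale: the
mesh-monotonicity analysis uses `r_min_px = 6` (≈ half the inscribed
radius of the small-mesh cells), under which doubling the lattice spacing
doubles the median radius. The tissue procedure's 12-µm reporting
threshold plays exactly this role.

## Synthetic network and nuclei images

Network images are jittered square lattices: nodes on a `spacing_px` grid
displaced uniformly by ±`jitter_px`, joined to 4-neighbours, rasterized and
dilated to `fiber_width_px` (default 3 px). This reproduces the
interconnected, fully-tiled character of the FRC network with a
controllable gap-size distribution; it does not attempt curved fibers,
variable fiber brightness, or out-of-plane structure. The fluorescence
model is generic: Gaussian PSF blur (σ = 0.7 px) of the fiber mask scaled
to `photon_scale` (default 100) photons, Poisson shot noise, plus Gaussian
read noise (SD 2). At these defaults Otsu binarization recovers the
ground-truth mask to ≥ 99% pixel agreement; the free-space mask emitted by
the generator is exact by construction.

Nuclei fields place Gaussian-profile nuclei (radius 4 px, amplitude 100,
profile σ = radius/1.5) by rejection sampling with a minimum centroid
separation (default 16 px = 2 diameters) plus read noise. Real DAPI
fields have touching and overlapping nuclei, intensity variation and
out-of-focus light; passing the recovery tests therefore demonstrates the
pipeline's correctness at the stated spacing/SNR conditions, not watershed
performance on densely packed tissue.

## T cell packing density

The nuclear plane is despeckled (3×3 median) and blurred (Gaussian σ = 2 px,
the macro's stated parameters), thresholded by Otsu ("thresholding" was
otherwise unspecified), and split by watershed seeded at distance-transform
maxima at least `peak_min_distance_px` apart (default 8 px ≈ one expected
nucleus diameter). Components below `min_area_px` (default 25% of the
median segmented area) are discarded. Nuclei whose **centroid** falls in
the PDPN⁺ exclusion mask are cleared — whether the original macro excluded
by centroid or by any overlap is unknown; the centroid rule is declared.
Density is count ÷ ROI area × 100 µm², with the **full** ROI area as the
denominator (not ROI minus PDPN⁺ area); the alternative is switchable and
the choice is recorded in output provenance.

## Ablation recoil

Displacement is the change in separation of two landmark tracks relative to
the pre-cut baseline (mean separation over all pre-cut frames by default; a
last-frame-only option exists since the original measurement may have used
a single reference frame). The initial recoil velocity is the displacement
at the first post-cut frame divided by the frame interval (0.521 s default,
the confocal scan speed used for these movies). The optional least-squares
fit of d(t) = A·(1 − e^(−t/τ)) (times measured from the cut, first post-cut
frame at one interval) is provided for smoothing and property testing; the
tissue analysis itself plots curves without fitting a model. A flat trace
leaves τ unidentifiable and is flagged; non-convergence is flagged with the
raw trace still usable. The synthetic generator snaps the cut to the frame
grid so the first post-cut sample is exactly A·(1 − e^(−Δt/τ)), making
noise-free recovery exact. Landmark positions are consumed as CSV tracks,
mirroring manual measurement; automatic cut detection is out of scope.

## Tether mechanics

Calibration uses equipartition, k = k_B·T / Var(x) (k_B = 0.0138065
pN·nm/K, T = 310.15 K default — cells are held at 37 °C), requiring ≥ 100
samples of a tether-free stationary stretch. At the 90-ms sampling of
these traces a power-spectral (corner-frequency) calibration is not
resolvable, so it is out of scope. The tether step is located by the split
maximizing |Δmean| / pooled SD; the search walks left to the *earliest*
significant step so a multi-step trace keeps the first pull, flags
`multi_step`, and truncates the plateau before the second step. Windows
exclude a 3-frame guard band; a best split below 3 pooled SDs flags
`no_step`. Force is F_T = kΔx with Δx the |mean(plateau) − mean(baseline)|
in nm, reported in pN alongside k and Δx separately so any normalized
variant (e.g. per-µm axes) can be recomputed downstream; no normalization
by tether length or bead size is guessed.

The bead generator is an Ornstein–Uhlenbeck process with the *exact*
discrete-time update (x_{n+1} = φx_n + √(σ²(1−φ²))·ξ, φ = e^(−Δt/τ_r)),
started in the stationary distribution, so the positional variance equals
k_B·T/k analytically at any sampling interval — no Euler discretization
bias. Default relaxation time 10 ms makes 90-ms samples effectively
independent.

## Osmotic swelling

Per-cell diameters (manual-ROI equivalents, every 30 s) are normalized by
the first-frame diameter d₀. Readouts: linearly interpolated ratio at
15 min, and trapezoidal AUC over the first 20 min. By default the AUC
integrates (ratio − 1) so an isotonic control integrates to ≈ 0; whether
the original analysis subtracted the baseline is unknown, so raw-ratio mode
is provided and the mode is recorded in every summary. Osmolarity recipes
(isotonic 137 mM NaCl; 50 mOsm as a 1/6 dilution; mannitol-restored 330
mOsm control) are condition metadata, not computed chemistry. The
generator uses an exponential approach to a plateau ratio,
ratio(t) = 1 + (plateau − 1)(1 − e^(−rate·t)), with closed-form AUC used as
the test oracle.

## Fiber scoring

Fiber ROIs are polylines rasterized and widened to `width_px` (default 3).
A fiber is "in network" when ≥ 50% of its sampled pixels fall in the PDPN⁺
mask; only in-network fibers enter the percentages. Channel positivity is
background-relative: positive iff the fiber's mean intensity exceeds the
background mean by z (default 2) background SDs, where background = in-
network pixels not on any fiber, estimated per image (whether the original
analysis thresholded per image or per experiment is unknown; per-image is
declared). This makes calls invariant to uniform intensity rescaling. A
zero-variance background falls back to an absolute mean comparison and is
flagged. "Matrix-aligned" (perlecan) adds an overlap criterion — ≥ 50% of
fiber pixels over pixelwise channel-positive area — since "aligned" is not
operationally defined anywhere; both the intensity and overlap values are
recorded per fiber.

## Proliferation tracking

Detections are linked frame-to-frame by greedy mutual-nearest-neighbour
matching within `max_disp_px` (default 5), with one-frame gap closure.
A division is a track ending at frame f with ≥ 2 tracks starting at f ± 1
within `search_radius_px` (default 15 ≈ 2 nucleus diameters) of its last
position, each persisting ≥ 3 frames; the two nearest daughters are
assigned, each to at most one parent. A new track with no terminating
parent nearby is an entering cell, never a division — conservative
counting. Divisions per cell = events ÷ n₀ with n₀ fixed at the first
frame (cells leaving the field do not change the divisor), plus the
cumulative normalized curve.

The movie generator gives each cell an exponential division clock
(per-cell rate per hour); daughters appear at ±`daughter_offset_px`
(default 6) along a random axis while the parent disappears, and inherit
clocks offset by a refractory age (default 2 h) so newborn tracks persist
long enough to be recognized. The offset deliberately exceeds the default
linking displacement so a mitosis reads as one track ending and two
starting — the signature the detector keys on; divisions are also not
scheduled within the last 3 frames, where daughters could not persist.
With `daughter_min_age_h = 0` the process is a pure Yule process with
expected event count n₀(e^{rT} − 1), used as the Monte-Carlo oracle. Real
nuclei movies contain focus drift, detection dropouts and crossing cells
that this generator only partially emulates (motility is a Gaussian random
walk; one-frame dropouts are covered by gap closure).

## Problem sizes and defaults in the test suite

Synthetic study conditions: 256×256 network images at 0.5 µm/px (mesh
20 px vs 40 px for the stretching contrast), 30-nucleus fields at 2-diameter
separation, recoil traces of 25 s at 0.521 s with noise SD 0.05 µm, bead
traces of 10⁴ samples at 90 ms, swelling traces of 30 min at 30 s, division
movies of 72 h at 0.5 h with rates 0.004–0.013 h⁻¹ (soft gel → glass;
chosen to span ≈0.3–1.3 divisions per cell over 72 h, a realistic
fibroblast range). Cohort checks use 100 replicates with 30 traces / 40
cells / 4 movies per replicate; oracle equivalence uses 200 random masks up
to 64×64. The full suite runs in a few minutes on one CPU.

## Known limitations

* All stages are 2-D; z-stacks are consumed via maximum projection and no
  volumetric counting is attempted.
* The gap packing restricts circle centers to pixel centers (as any
  raster implementation must); sub-pixel centers could admit marginally
  larger circles.
* Segmentation is tuned for well-separated, roughly isotropic nuclei;
  heavily overlapping nuclei will under-count.
* The division detector cannot see divisions whose daughters leave the
  field or merge within 3 frames, and events in the last frames of a movie
  are undetectable by construction.
* Membrane-tension conversion from tether force requires bending-rigidity
  assumptions and is deliberately not computed.
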