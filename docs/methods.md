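# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind each module. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Track data model (`trackcore`)

Tracks are time-ordered positions in μm with 0-based frame indices and
times in seconds; datasets carry the frame interval, pixel size and
field extent of one movie. All quantities are stored in physical units
internally; unit conversion (e.g. pixel → μm) happens only at the I/O
boundary. Tracks shorter than two points are dropped at read time with
a logged count. Gaps from missed detections are retained as non-uniform
time steps rather than interpolated. The duration filter uses a strict
inequality (duration > threshold); both thresholds used in the analyses
(0.9 s and 1 s) are caller-supplied parameters rather than a single
hard-coded value, since different analyses legitimately use different
cuts.

## Trajectory simulation (`motion_sim`)

Vesicles occupy one of three motion states — Brownian with per-axis
step sd √(2·D·dt), immobile, or directed at speed v along a persistent
direction — and switch with memoryless exponential waiting times
(switching kinetics in live cells are not characterized; the
exponential is the maximum-entropy choice). Directed runs are straight
lines with optional small angular diffusion; curvilinear cytoskeletal
geometry is deliberately not modelled because the downstream statistics
(efficiency, α) only need the straight-line limit to be exact.
Boundaries are reflecting on all walls, which conserves particle number
— a property the FLIP simulation depends on.

Defaults represent the study conditions the package emulates: D in the
0.1–0.3 μm² s⁻¹ range, directed speed 1–2 μm s⁻¹, frame intervals
10–100 ms, and a 14 μm cube for 3D scenes.

Rendering places a 2D Gaussian PSF (lateral sd 0.1 μm) per spot on a
0.11 μm pixel grid; for 3D scenes the amplitude is weighted by
exp(−z′²/(2·σ_ax²)) with σ_ax = 0.5 μm, emulating a confocal slice.
Noise is a constant background plus Poisson shot noise plus Gaussian
read noise; spots fainter than 10⁻³ of nominal amplitude are culled for
speed. The PSF and noise parameters are configuration, not assertions:
fixture SNR brackets the low-SNR regime of fast capture. The mapping
from a target in-focus areal density to a 3D particle count treats the
visible slab as ±1 axial sigma; with the defaults this maps
5.57 μm⁻² to ~15,300 particles in the cube, the scale of a whole-cell
vesicle population.

## Detection and linking (`tracker`)

Detection is scale-normalized Laplacian-of-Gaussian maxima above a
quality threshold, refined to subpixel by an intensity-weighted
centroid in a 5×5 window. Linking is greedy global nearest-neighbour:
candidate (track end, detection) pairs within a displacement gate are
sorted by distance and assigned one-to-one; ends may survive up to
`max_gap` missed frames with the gate scaled by the number of skipped
intervals. The default gate is 3·√(4·D_max·dt). This is intentionally
not a reimplementation of any published tracker's assignment machinery:
the benchmark only needs a linker whose failure mode under crowding is
the physical one (mislinks when the frame-to-frame displacement becomes
comparable to the nearest-neighbour spacing).

The benchmark recovers D from the ensemble MSD with a straight-line
fit (free intercept, first 4 lags). The free intercept absorbs the
static localization-error offset (MSD_apparent = 4DΔt + 4σ_loc²), so
differences from ground truth isolate detection/linking error rather
than localization noise. Ground truth uses the simulator's true
correspondences projected in-plane and the same estimator. Benchmark
claims are directional (degradation with density and with slower
capture), asserted on medians over ≥5 seeded replicates; no numeric
equality with any published accuracy curve is asserted, since the
external tracker's settings are not public.

## Track statistics (`trackstats`)

The time-averaged MSD averages squared displacements over all pairs at
each frame lag (gaps contribute no pair). α and D come from a
least-squares line on log MSD vs log Δt over the first 4 lags (common
single-particle-tracking practice; window configurable), with
D = exp(intercept)/4 in 2D. Efficiency follows the trajectory-classifier
convention E = |r_N − r_1|²/((N−1)·Σ|r_{i+1} − r_i|²) with the N−1
factor fixed so a straight uniform track scores exactly 1; zero total
displacement maps to E = 0. Analysis is 2D; z is ignored when present.

Features per track: α; neighbours (time-overlapping tracks whose mean
position lies within 1 μm of this track's mean — the temporal
convention is a package choice, since co-existence can be defined
several ways); density = neighbours/π per μm²; cumulative distance and
time; speed = cumdist/cumtime (per-cell "mean speed" averages this
per-track ratio, not instantaneous speeds); wide (maximum
point-to-point distance); and the Katz fractal dimension
fd = log n/(log n + log(wide/cumdist)), chosen because it needs no
tuning scale and is exact (fd = 1) for straight tracks.

## Mobility profiles (`mobility_profile`)

Features are z-scored per column over the pooled multi-marker table
(features span incompatible units), then embedded jointly with PCA —
one embedding for all markers, so marker shapes are comparable.
Component signs are fixed (largest loading positive) for determinism.
Per-marker densities use a Gaussian KDE with Scott's rule on a shared
64×64 grid spanning the pooled PC1/PC2 range ±5%, renormalized to sum
to 1. The shape distance is the L1 sum |a − b| (range [0, 2] for
normalized shapes) — the simplest "total distance"; the classification
is robust to the metric choice, so simplicity wins. Marker clustering
is average-linkage agglomeration on the dissimilarity matrix with a
k-cut (other linkages selectable).

One caveat the test suite documents: after per-column z-scoring, a mean
shift confined to a *single* feature cannot dominate PC1 (every column
is rescaled to unit variance), so separability tests use shifts across
correlated features, which standardization preserves.

The synthetic study used to validate the pipeline has eight markers in
three generative classes — five purely diffusive (D = 0.10–0.30
μm² s⁻¹), two directed-rich (60% directed tracks at 1–2 μm s⁻¹), one
pure-directed — with 60 tracks per marker of varied length (10–50
steps at 60 ms). Class recovery is asserted on at least 9 of 10 seeds.

## Photobleaching kinetics (`photokinetics`)

Curves are background-subtracted and normalized so the pre-bleach mean
is 1. The model is y(t) = y0 + A·e^(−(t−x0)/τ): the decaying form (a
growing exponential cannot describe bounded recovery), with the sign of
A distinguishing recovery (A < 0) from loss (A > 0). x0 is fixed at the
first post-bleach sample by default. Weights are 1/sd per time point
when enabled (the FRAP convention). The immobile fraction is
plateau-based: 1 − (y0 − y_bleach)/(y_pre − y_bleach) with y_bleach the
fitted value at x0. Flat traces are rejected with diagnostics rather
than returning a degenerate fit. Half-times convert as t½ = τ·ln 2.

Stokes–Einstein uses T = 310 K (imaging at 37 °C) and cytoplasmic
viscosity η = 4.4×10⁻² Pa s by default; both are parameters. The
capture-limited "apparent D" from a mean travel distance and half-time
ships several explicitly named dimensional scalings (L²/(6t), L²/(4t),
L²/(2t)) and records which was used, because no single convention is
canonical for that back-of-envelope estimate; none of them is asserted
to reproduce any particular measured value.

## FLIP simulation (`flip_sim`)

100 vesicles start uniformly distributed over a 15 μm radius disc
(including inside the bleach zone) and take 2D Brownian steps every
60 ms with radial reflection at the cell boundary. A bleach pulse of
60 ms fires every 3 s; during a pulse, every active vesicle inside the
bleach disc (radius 2.6–2.8 μm in five steps, centred by default,
offset configurable) is permanently inactivated. With sim_dt equal to
the pulse duration this is one containment check per pulse. The first
pulse fires one interval after t = 0 (configurable). Vesicle number is
conserved — no creation or fusion during the simulated period.

Survival is recorded at pulse times (it only changes there); the
half-inactivation time is the linearly interpolated first crossing of
0.5, NaN (censored) if never reached. Half-time estimates average the
full 5-radius × 10-replicate cross; censored replicates are excluded
with a warning. Calibration bisects D against a target half-time,
re-using the same seed at every evaluation (common random numbers) so
the simulated half-time is effectively monotone in D; monotonicity is
verified at the bracket endpoints. The returned D carries the
replicate spread of the achieved half-time.

Two sanity anchors: with D = 0 the survival plateau is 1 − (a/R)²
(only vesicles born inside the disc ever bleach), and with the laser
continuously on the half-time agrees within a factor of two with the
2D narrow-target mean-first-passage form (R²/2D)(ln(R/a) − 3/4)·ln 2.

## Image-stack analyses (`eventdetect`)

Exocytosis detection: maximum-intensity projection → local maxima at
least 20 counts above the projection median (prominence), ≥4 px apart →
circular ROI (radius 2 px) intensity traces → per-trace normalization
to the baseline median → temporal peaks of relative amplitude ≥ 0.2.
The thresholds were calibrated on synthetic fixtures (flash amplitude
10× noise sd detects cleanly; pure noise yields zero events) and are
all parameters. Rates are events per μm² of mask per minute of movie.
Event profiles align traces at their peaks, min-max normalize to
[0, 1], and average; the rise time is the 10→90% interval of the
average rising flank (the 10–90 convention is a package choice).

Distance maps use the Euclidean distance transform with anisotropic
voxel sampling, restricted to in-cell voxels with target voxels
excluded; the summary is the median. Relocalization measures mean
masked intensity per frame, background-subtracted and normalized to
the pre-treatment mean, and hands off to the exponential fitter.
Segmentation of real data is out of scope: masks are supplied (or
thresholded), not learned.

## Problem sizes and testing scope

The test suite and analysis drivers run everything at desk scale:
hundreds of tracks per dataset, benchmark movies of 40 frames on a
128² grid (up to ~15,000 particles in the 3D scene at the highest
density), 10 FLIP replicates per radius step, and 10 seeds for the
clustering study. These sizes were chosen so the full pipeline
exercises every claimed property while remaining quick to re-run.

What passing tests on synthetic data do and do not show: the generator
reproduces the statistical structure the methods assume (Gaussian
steps, state switching, PSF + Poisson/read noise, flash-shaped events)
but not everything real movies contain — no fluorophore blinking or
photobleaching during rendering, no motion blur within an exposure, no
curved cytoskeletal paths, no spatially varying background, and
vesicles that never fuse or split. Results on real data therefore
depend on detection/segmentation quality in ways these tests cannot
certify; the oracle-equivalence and analytic-limit tests certify the
estimators themselves, and the benchmark certifies the direction and
rough magnitude of density/frame-rate biases.
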