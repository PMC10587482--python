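# vesikin

Analysis toolkit for asking how small trafficking vesicles move inside
cells: is transport dominated by motor-driven, directed movement along
microtubules, or by passive diffusion? The package covers the full
computational pipeline needed to answer that question from live-cell
imaging-style data — single-particle track statistics, tracking-accuracy
benchmarking, photobleaching (FRAP/FLIP) kinetics with a Brownian
bleaching simulator, physical size/diffusion predictions, 3D proximity
maps, and automated exocytosis detection — and ships a synthetic-data
generator so every stage runs and is tested without microscope data.

It is aimed at cell biologists and image analysts working with
intracellular nanovesicles (INVs, ~30–60 nm trafficking vesicles) and
similar sub-resolution cargo.

## What it computes

- **Track mobility** (`trackstats`): the time-averaged mean squared
  displacement of a track fits MSD(Δt) = 4·D·Δt^α in 2D; α ≈ 1 is normal
  diffusion, α < 1 confined, α > 1 directed. Directed transport is
  flagged by the track-linearity *efficiency*
  E = |r_N − r_1|² / ((N−1)·Σ|r_{i+1} − r_i|²), which is 1 for straight
  uniform motion.
- **Mobility profiles** (`mobility_profile`): per-track eight-feature
  vectors (α, neighbours, density, cumdist, cumtime, speed, wide,
  fractal dimension) are z-scored, embedded with PCA, turned into
  per-marker kernel-density shapes in PC space, compared by L1 "total
  distance", and clustered hierarchically into motion classes.
- **Photobleaching kinetics** (`photokinetics`): recovery/loss curves
  are normalized to the pre-bleach level and fit with
  y(t) = y0 + A·e^(−(t−x0)/τ); a FRAP half-time converts to a diffusion
  coefficient via the corrected Soumpasis relation
  D = (r_e² + r_n²)/(8·τ½); particle size maps to D via Stokes–Einstein
  D = k_B·T/(6π·η·r) with cytoplasmic viscosity η = 4.4×10⁻² Pa s.
- **FLIP simulation** (`flip_sim`): Brownian vesicles in a circular cell
  are inactivated by periodic bleach pulses in a small disc; bisection
  on D matches the simulated half-inactivation time to an experimental
  one.
- **Tracking benchmark** (`motion_sim` + `tracker`): 3D diffusion in a
  14 μm cube rendered into confocal-plane movies, re-detected and
  re-linked, quantifies how recovered D degrades with particle density
  and frame interval.
- **Image-stack analyses** (`eventdetect`): exocytic flash detection and
  rates (events μm⁻² min⁻¹), peak-aligned event profiles, 3D Euclidean
  distance maps, and relocalization time courses.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write tables under `results/` (run 01 before 02):

```sh
python analysis/01_simulate_tracks.py
python analysis/02_mobility_stats.py
```

prints, among other lines:

```
brownian: 200 tracks, median alpha 1.00, median D 0.195 um^2/s, directed fraction 0.00 (>0.142)
three_state: 200 tracks, median alpha 1.27, median D 0.190 um^2/s, directed fraction 0.30 (>0.142)
```

The pure-Brownian dataset (generated at D = 0.2 μm² s⁻¹) is recovered
with median α = 1.00 and median D = 0.195 μm² s⁻¹, and no track exceeds
the directed-efficiency threshold; the three-state dataset picks up its
directed sub-population. The FLIP calibration driver,

```sh
python analysis/05_flip_calibration.py
```

prints:

```
target half-time 298 s -> calibrated D = 0.354 um^2/s (achieved 295 +/- 47 s over 50 replicates)
```

i.e. vesicles diffusing at ~0.35 μm² s⁻¹ lose half the cell's
fluorescent pool in ~5 minutes of pulsed bleaching of a disc covering
3.2% of the cell — diffusion alone is fast enough to pass every vesicle
through a small bleach zone in minutes. The other drivers cover the
tracking benchmark (03), curve fitting and Stokes–Einstein tables (04),
marker clustering (06), exocytosis rates (07) and proximity maps (08).

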