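"""Synthetic vesicle trajectories and confocal-plane movie rendering.

Implements the generative model every downstream stage assumes: vesicles
occupy one of three motion states — Brownian (diffusion coefficient D),
immobile, or directed at speed v along a persistent direction — and switch
between states with memoryless exponential waiting times. Trajectories are
confined to a box with reflecting boundaries. 3D trajectories can be
rendered into a confocal-plane image stack: each spot is a 2D Gaussian of
width ``psf_sigma_lateral`` whose amplitude falls off as
``exp(-z'^2 / (2 * axial_weight_sigma^2))`` with distance z' from the
focal plane, with Poisson shot noise and Gaussian read noise on top of a
constant background.

The module also provides :func:`simulate_flash_movie` — 2D image stacks
containing transient exocytic "flash" events used by the event-detection
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .trackcore import Track, TrackDataset

__all__ = [
    "MotionModel",
    "ImagingModel",
    "simulate_tracks",
    "simulate_box3d",
    "render_movie",
    "simulate_flash_movie",
    "write_movie_tiff",
    "read_movie_tiff",
]


def write_movie_tiff(stack: np.ndarray, path) -> None:
    """Write an image stack as a multi-page 16-bit TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.uint16))


def read_movie_tiff(path) -> np.ndarray:
    """Read a multi-page TIFF into a (frames, rows, cols) array."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return stack

BROWNIAN, IMMOBILE, DIRECTED = "brownian", "immobile", "directed"
_ALL_STATES = (BROWNIAN, IMMOBILE, DIRECTED)


@dataclass
class MotionModel:
    """Three-state motion model for vesicle trajectories.

    Parameters
    ----------
    D : float
        Diffusion coefficient of the Brownian state, μm² s⁻¹.
    v : float
        Speed of the directed state, μm s⁻¹.
    state_set : tuple of str
        Subset of {"brownian", "immobile", "directed"} the model may occupy.
    switch_rate : float
        Per-second rate of leaving the current state (exponential waiting
        times); on a switch the new state is drawn uniformly from the other
        members of ``state_set``. 0 disables switching.
    dt : float
        Time step, s.
    duration : float
        Track duration, s.
    angular_sigma : float
        Per-step standard deviation (radians, 2D) of the directed-state
        heading; 0 gives straight-line runs.
    """

    D: float = 0.3
    v: float = 1.5
    state_set: tuple[str, ...] = (BROWNIAN, IMMOBILE, DIRECTED)
    switch_rate: float = 0.0
    dt: float = 0.06
    duration: float = 3.0
    angular_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0 or self.v < 0 or self.switch_rate < 0:
            raise ValueError("D, v and switch_rate must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        unknown = set(self.state_set) - set(_ALL_STATES)
        if unknown:
            raise ValueError(f"unknown states: {sorted(unknown)}")
        if not self.state_set:
            raise ValueError("state_set must be non-empty")


@dataclass
class ImagingModel:
    """Confocal-plane rendering parameters.

    ``noise_background`` is a constant offset (counts), ``noise_read_sd``
    the Gaussian read-noise standard deviation (counts) and
    ``photon_scale`` converts spot amplitude to expected photon counts for
    the Poisson shot-noise draw. ``axial_weight_sigma`` sets how quickly a
    spot fades as it leaves the focal plane.
    """

    pixel_size: float = 0.11
    psf_sigma_lateral: float = 0.1
    axial_weight_sigma: float = 0.5
    exposure: float = 0.01
    frame_interval: float = 0.06
    noise_background: float = 100.0
    noise_read_sd: float = 2.0
    photon_scale: float = 1.0
    amplitude: float = 600.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        for name in ("pixel_size", "psf_sigma_lateral", "axial_weight_sigma",
                     "exposure", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.frame_interval < self.exposure:
            raise ValueError("frame_interval must be >= exposure")


def _reflect(pos: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """Fold positions back into [0, extent] per axis (reflecting walls)."""
    period = 2.0 * extent
    pos = np.mod(pos, period)
    over = pos > extent
    pos[over] = (period * np.ones_like(pos))[over] - pos[over]
    return pos


def _sample_states(model: MotionModel, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Per-step state index sequence with exponential waiting times."""
    states = np.empty(n_steps, dtype=np.int8)
    members = list(model.state_set)
    cur = rng.integers(len(members))
    t = 0
    while t < n_steps:
        if model.switch_rate > 0 and len(members) > 1:
            dwell = max(1, int(np.ceil(rng.exponential(1.0 / model.switch_rate) / model.dt)))
        else:
            dwell = n_steps
        states[t : t + dwell] = cur
        t += dwell
        if len(members) > 1:
            cur = (cur + 1 + rng.integers(len(members) - 1)) % len(members)
    return states


def simulate_tracks(
    model: MotionModel,
    n: int,
    extent: float | tuple[float, ...] = 20.0,
    seed: int | np.random.Generator = 0,
    ndim: int = 2,
) -> TrackDataset:
    """Simulate ``n`` three-state trajectories in a reflecting box.

    Brownian steps are Normal(0, sqrt(2*D*dt)) per axis, immobile steps are
    zero, directed steps advance v*dt along a persistent unit direction
    (with optional angular diffusion in 2D). Fully reproducible from
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model.dt >= model.duration:
        raise ValueError("dt must be < duration")
    rng = np.random.default_rng(seed)
    extent_arr = np.broadcast_to(np.asarray(extent, dtype=float), (ndim,)).copy()
    n_steps = int(round(model.duration / model.dt))
    times = np.arange(n_steps + 1) * model.dt
    members = list(model.state_set)
    sigma = np.sqrt(2.0 * model.D * model.dt)

    tracks = []
    for i in range(n):
        states = _sample_states(model, n_steps, rng)
        steps = np.zeros((n_steps, ndim))
        is_brownian = np.array([members[s] == BROWNIAN for s in states])
        is_directed = np.array([members[s] == DIRECTED for s in states])
        if is_brownian.any():
            steps[is_brownian] = sigma * rng.standard_normal((is_brownian.sum(), ndim))
        if is_directed.any():
            direction = rng.standard_normal(ndim)
            direction /= np.linalg.norm(direction)
            if ndim == 2 and model.angular_sigma > 0:
                theta0 = np.arctan2(direction[1], direction[0])
                theta = theta0 + np.cumsum(
                    model.angular_sigma * rng.standard_normal(n_steps)
                )
                headings = np.stack([np.cos(theta), np.sin(theta)], axis=1)
            else:
                headings = np.broadcast_to(direction, (n_steps, ndim))
            steps[is_directed] = model.v * model.dt * headings[is_directed]
        start = rng.uniform(0, extent_arr, size=ndim)
        pos = start + np.cumsum(steps, axis=0)
        pos = np.vstack([start, pos])
        pos = _reflect(pos, extent_arr)
        tracks.append(
            Track(id=str(i), frames=np.arange(n_steps + 1), times=times, positions=pos)
        )
    return TrackDataset(
        tracks=tracks,
        frame_interval=model.dt,
        field_extent=tuple(extent_arr),
        metadata={"model": model, "seed": seed if isinstance(seed, int) else None},
    )


def simulate_box3d(
    D: float,
    n: int,
    box: float = 14.0,
    dt: float = 0.06,
    duration: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> TrackDataset:
    """Pure Brownian diffusion of ``n`` particles in a 3D reflecting cube."""
    model = MotionModel(D=D, state_set=(BROWNIAN,), dt=dt, duration=duration)
    return simulate_tracks(model, n=n, extent=box, seed=seed, ndim=3)


def density_to_particle_count(
    density: float, box: float = 14.0, axial_weight_sigma: float = 0.5
) -> int:
    """Particles needed in a cube for a given in-focus areal density.

    A spot is counted as in focus when it lies within ±1 axial weighting
    sigma of the focal plane, so the visible slab has thickness
    2*axial_weight_sigma and the 3D count is density * box² * box / slab.
    (For a 14 μm cube with a 0.5 μm axial sigma this maps 5.57 μm⁻² to
    ~15,300 particles, matching the scale of a whole-cell vesicle count.)
    """
    slab = 2.0 * axial_weight_sigma
    return int(round(density * box * box * box / slab))


def render_movie(
    ds: TrackDataset,
    im: ImagingModel,
    seed: int | np.random.Generator = 0,
    focal_plane: float | None = None,
) -> np.ndarray:
    """Render a dataset into a uint16 image stack (frames, rows, cols).

    2D datasets are rendered in-plane; 3D datasets require ``focal_plane``
    (z position of the confocal slice, μm) and spot amplitudes are
    weighted by the axial Gaussian. Spots fainter than 1e-3 of the nominal
    amplitude are culled for speed.
    """
    if ds.field_extent is None:
        raise ValueError("dataset needs field_extent to be rendered")
    extent_xy = ds.field_extent[:2]
    if im.pixel_size >= min(extent_xy):
        raise ValueError("pixel_size must be smaller than the field extent")
    rng = np.random.default_rng(seed)
    ndim = ds.ndim
    if ndim == 3 and focal_plane is None:
        raise ValueError("3D dataset requires focal_plane")

    n_cols = int(np.ceil(extent_xy[0] / im.pixel_size))
    n_rows = int(np.ceil(extent_xy[1] / im.pixel_size))
    n_frames = int(max(t.frames.max() for t in ds.tracks)) + 1
    if n_frames < 1 or not ds.tracks:
        raise ValueError("empty dataset")

    # gather (frame, x, y, weight) for every point
    stack = np.zeros((n_frames, n_rows, n_cols), dtype=float)
    sigma_px = im.psf_sigma_lateral / im.pixel_size
    half = max(3, int(np.ceil(4 * sigma_px)))
    win = np.arange(-half, half + 1)

    for track in ds.tracks:
        xs = track.positions[:, 0] / im.pixel_size
        ys = track.positions[:, 1] / im.pixel_size
        if ndim == 3:
            dz = track.positions[:, 2] - focal_plane
            weights = np.exp(-(dz**2) / (2.0 * im.axial_weight_sigma**2))
        else:
            weights = np.ones(track.n_points)
        for k in range(track.n_points):
            if weights[k] < 1e-3:
                continue
            f = int(track.frames[k])
            cx, cy = xs[k], ys[k]
            ix, iy = int(round(cx)), int(round(cy))
            gx = np.exp(-((win + ix - cx) ** 2) / (2 * sigma_px**2))
            gy = np.exp(-((win + iy - cy) ** 2) / (2 * sigma_px**2))
            patch = im.amplitude * weights[k] * np.outer(gy, gx)
            r0, r1 = iy - half, iy + half + 1
            c0, c1 = ix - half, ix + half + 1
            pr0, pc0 = max(0, -r0), max(0, -c0)
            r0, c0 = max(0, r0), max(0, c0)
            r1, c1 = min(n_rows, r1), min(n_cols, c1)
            if r1 <= r0 or c1 <= c0:
                continue
            stack[f, r0:r1, c0:c1] += patch[pr0 : pr0 + (r1 - r0), pc0 : pc0 + (c1 - c0)]

    expected = (stack + im.noise_background) * im.photon_scale
    if im.shot_noise:
        noisy = rng.poisson(expected) / im.photon_scale
    else:
        noisy = expected / im.photon_scale
    if im.noise_read_sd > 0:
        noisy = noisy + im.noise_read_sd * rng.standard_normal(stack.shape)
    return np.clip(np.round(noisy), 0, 65535).astype(np.uint16)


def simulate_flash_movie(
    n_frames: int,
    shape: tuple[int, int],
    flash_positions: np.ndarray,
    flash_frames: np.ndarray,
    pixel_size: float = 0.11,
    frame_interval: float = 0.5,
    amplitude: float = 200.0,
    rise_frames: int = 2,
    decay_frames: int = 6,
    psf_sigma: float = 0.15,
    noise_sd: float = 5.0,
    background: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Movie of transient exocytic flash events on a noisy background.

    Each flash is a 2D Gaussian spot (μm coordinates) whose amplitude
    rises linearly over ``rise_frames`` and decays exponentially with time
    constant ``decay_frames`` afterwards. Returns a uint16 stack.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    stack = np.full((n_frames, n_rows, n_cols), background, dtype=float)
    sigma_px = psf_sigma / pixel_size
    half = max(3, int(np.ceil(4 * sigma_px)))
    win = np.arange(-half, half + 1)
    flash_positions = np.atleast_2d(np.asarray(flash_positions, dtype=float))
    flash_frames = np.atleast_1d(np.asarray(flash_frames, dtype=int))
    for (x, y), f0 in zip(flash_positions, flash_frames):
        cx, cy = x / pixel_size, y / pixel_size
        ix, iy = int(round(cx)), int(round(cy))
        gx = np.exp(-((win + ix - cx) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((win + iy - cy) ** 2) / (2 * sigma_px**2))
        patch = np.outer(gy, gx)
        for f in range(max(0, f0 - rise_frames), n_frames):
            if f < f0:
                a = amplitude * (1.0 - (f0 - f) / (rise_frames + 1))
            else:
                a = amplitude * np.exp(-(f - f0) / decay_frames)
            if a < 0.5 and f >= f0:
                break
            r0, r1 = iy - half, iy + half + 1
            c0, c1 = ix - half, ix + half + 1
            pr0, pc0 = max(0, -r0), max(0, -c0)
            r0, c0 = max(0, r0), max(0, c0)
            r1, c1 = min(n_rows, r1), min(n_cols, c1)
            if r1 <= r0 or c1 <= c0:
                continue
            stack[f, r0:r1, c0:c1] += a * patch[pr0 : pr0 + (r1 - r0), pc0 : pc0 + (c1 - c0)]
    stack += noise_sd * rng.standard_normal(stack.shape)
    return np.clip(np.round(stack), 0, 65535).astype(np.uint16)
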