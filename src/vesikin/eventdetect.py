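"""Image-stack analyses: exocytosis detection, event profiling, 3D
distance maps, and relocalization time courses.

Exocytic fusion events (transient bright flashes of a pH-sensitive
reporter) are found by projecting the movie, centring small ROIs on
projection maxima, extracting per-ROI intensity traces, and detecting
temporal peaks; the event rate is reported per μm² per minute over the
cell mask. Distance maps give, for every in-cell voxel, the Euclidean
distance to the nearest target (e.g. mitochondrial) voxel, summarized by
the median. Relocalization quantifies mean masked intensity per frame,
normalized to the pre-treatment level, for exponential fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.feature import peak_local_max

from .photokinetics import RecoveryCurve, normalize_curve

__all__ = [
    "ExocytosisEvent",
    "EventRateResult",
    "DistanceMapResult",
    "detect_events",
    "event_profiles",
    "distance_map",
    "measure_relocalization",
]


@dataclass
class ExocytosisEvent:
    """One detected fusion event: location (μm), peak frame, the
    normalized ROI trace around the peak, and summary amplitudes."""

    position: tuple[float, float]
    frame: int
    trace: np.ndarray
    times: np.ndarray
    peak_amplitude: float


@dataclass
class EventRateResult:
    """Event count and rate per μm² per minute over the analysed mask."""

    n_events: int
    cell_area: float
    duration: float  # minutes
    rate: float

    def __post_init__(self) -> None:
        expected = self.n_events / (self.cell_area * self.duration)
        if abs(self.rate - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("rate must equal n_events/(cell_area * duration)")


@dataclass
class DistanceMapResult:
    """Distances (μm) from every measurable voxel to the target surface."""

    voxel_distances: np.ndarray
    median_distance: float


def _roi_trace(stack: np.ndarray, cy: int, cx: int, radius: int) -> np.ndarray:
    yy, xx = np.ogrid[: stack.shape[1], : stack.shape[2]]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return stack[:, mask].mean(axis=1)


def detect_events(
    stack: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    maxima_prominence: float = 20.0,
    peak_threshold: float = 0.2,
    roi_radius: int = 2,
    min_separation_px: int = 4,
) -> tuple[list[ExocytosisEvent], EventRateResult]:
    """Automated exocytic-event detection and rate quantification.

    The stack is max-projected; projection maxima at least
    ``maxima_prominence`` above the projection median seed circular ROIs
    of ``roi_radius`` pixels; each ROI's intensity trace is normalized to
    its baseline (median) and peaks of relative amplitude above
    ``peak_threshold`` are counted as events. The rate is events per μm²
    (mask area) per minute (movie duration).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 10:
        raise ValueError("stack must have >= 10 frames")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    projection = stack.max(axis=0)
    floor = float(np.median(projection))
    candidates = peak_local_max(
        projection,
        min_distance=min_separation_px,
        threshold_abs=floor + maxima_prominence,
        exclude_border=roi_radius,
    )
    events: list[ExocytosisEvent] = []
    n_frames = stack.shape[0]
    for cy, cx in candidates:
        if not cell_mask[cy, cx]:
            continue
        trace = _roi_trace(stack, cy, cx, roi_radius)
        baseline = float(np.median(trace))
        if baseline <= 0:
            continue
        rel = trace / baseline - 1.0
        peaks, props = signal.find_peaks(rel, height=peak_threshold,
                                         prominence=peak_threshold)
        for p, amp in zip(peaks, props["peak_heights"]):
            events.append(ExocytosisEvent(
                position=(cx * pixel_size, cy * pixel_size),
                frame=int(p),
                trace=rel,
                times=(np.arange(n_frames) - p) * frame_interval,
                peak_amplitude=float(amp),
            ))
    area = float(cell_mask.sum()) * pixel_size**2
    duration_min = n_frames * frame_interval / 60.0
    rate = len(events) / (area * duration_min)
    return events, EventRateResult(
        n_events=len(events), cell_area=area, duration=duration_min, rate=rate
    )


def event_profiles(
    events: list[ExocytosisEvent],
    frame_interval: float,
    window: float = 5.0,
) -> dict:
    """Peak-aligned average profile and amplitude statistics of events.

    Each event's trace is clipped to ±``window`` seconds around its peak,
    min-max normalized to [0, 1], and averaged across events (offsets
    missing from a trace are excluded from the average at that offset).
    The rise time is the 10%→90% interval of the average rising flank.
    """
    if not events:
        raise ValueError("need >= 1 event")
    half = int(round(window / frame_interval))
    offsets = np.arange(-half, half + 1)
    aligned = np.full((len(events), len(offsets)), np.nan)
    for i, ev in enumerate(events):
        idx0 = int(np.argmin(np.abs(ev.times)))  # peak sample
        for j, off in enumerate(offsets):
            k = idx0 + off
            if 0 <= k < len(ev.trace):
                aligned[i, j] = ev.trace[k]
        lo = np.nanmin(aligned[i])
        hi = np.nanmax(aligned[i])
        if hi > lo:
            aligned[i] = (aligned[i] - lo) / (hi - lo)
    mean = np.nanmean(aligned, axis=0)
    sd = np.nanstd(aligned, axis=0)
    times = offsets * frame_interval

    # 10-90% rise on the average's rising flank (up to the peak offset)
    peak_idx = int(np.nanargmax(mean))
    rising = mean[: peak_idx + 1]
    t_rise = np.nan
    if len(rising) >= 2:
        t10 = np.interp(0.1, rising, times[: peak_idx + 1])
        t90 = np.interp(0.9, rising, times[: peak_idx + 1])
        t_rise = float(t90 - t10)
    return {
        "amplitudes": np.array([ev.peak_amplitude for ev in events]),
        "times": times,
        "mean_trace": mean,
        "sd_trace": sd,
        "rise_time": t_rise,
    }


def distance_map(
    target_mask: np.ndarray,
    cell_mask: np.ndarray,
    voxel_size: float | tuple[float, ...] = 1.0,
) -> DistanceMapResult:
    """Euclidean distance from in-cell voxels to the nearest target voxel.

    Target voxels themselves are excluded from the measurement; the
    transform respects anisotropic voxel sizes. Raises if the target is
    empty within the cell.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if target_mask.shape != cell_mask.shape:
        raise ValueError("masks must have the same shape")
    if not (target_mask & cell_mask).any():
        raise ValueError("target mask is empty within the cell")
    sampling = np.broadcast_to(np.asarray(voxel_size, dtype=float),
                               (target_mask.ndim,))
    edt = ndimage.distance_transform_edt(~target_mask, sampling=sampling)
    measurable = cell_mask & ~target_mask
    if not measurable.any():
        raise ValueError("no measurable voxels: target fills the cell")
    distances = edt[measurable]
    return DistanceMapResult(
        voxel_distances=distances, median_distance=float(np.median(distances))
    )


def measure_relocalization(
    stack: np.ndarray,
    target_mask: np.ndarray,
    background_region: np.ndarray,
    pretreatment_frames: int,
    frame_interval: float = 1.0,
) -> RecoveryCurve:
    """Mean masked intensity per frame, background-subtracted and
    normalized to the pre-treatment mean.

    ``target_mask`` may be a single 2D mask or one mask per frame. The
    returned curve feeds :func:`vesikin.photokinetics.fit_exponential`.
    """
    stack = np.asarray(stack, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    background_region = np.asarray(background_region, dtype=bool)
    if target_mask.ndim == 2:
        masks = np.broadcast_to(target_mask, stack.shape)
    else:
        masks = target_mask
    if masks.shape != stack.shape:
        raise ValueError("mask shape must match the stack")
    if not background_region.any():
        raise ValueError("background region is empty")
    raw = np.empty(stack.shape[0])
    bg = np.empty(stack.shape[0])
    for f in range(stack.shape[0]):
        m = masks[f]
        if not m.any():
            raise ValueError(f"target mask empty in frame {f}")
        raw[f] = stack[f][m].mean()
        bg[f] = stack[f][background_region].mean()
    times = np.arange(stack.shape[0], dtype=float) * frame_interval
    return normalize_curve(raw, bg, pretreatment_frames, times=times)
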