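"""Data model and I/O for single-particle tracks.

A :class:`Track` is one particle's time-ordered positions in micrometres;
a :class:`TrackDataset` is the calibrated collection of tracks from one
imaged cell or movie (shared frame interval, pixel size and field extent).
All positions are stored in μm and all times in seconds; unit conversion
happens only at the I/O boundary. Frame indices are 0-based internally
regardless of the source dialect.

Supported formats: the TrackMate XML export dialect (read, plus a writer
used to build synthetic fixtures) and a flat CSV dialect with header
``track_id,frame,t,x,y[,z][,intensity]`` (read/write).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "TrackDataset",
    "TrackFormatError",
    "read_tracking_xml",
    "write_trackmate_xml",
    "read_tracks_csv",
    "write_tracks_csv",
    "filter_min_duration",
]


class TrackFormatError(ValueError):
    """Raised when a track file violates the expected dialect."""


@dataclass(frozen=True)
class Track:
    """One particle's trajectory.

    Parameters
    ----------
    id : str
        Opaque identifier (unique within a dataset).
    frames : ndarray of int
        0-based frame indices, strictly increasing. Gaps (missed
        detections) are permitted and retained as non-uniform time steps.
    times : ndarray of float
        Acquisition times in seconds, strictly increasing.
    positions : ndarray, shape (n, ndim)
        Coordinates in μm; ndim is 2 or 3 and constant within the track.
    intensities : ndarray or None
        Optional arbitrary-unit spot intensities, one per point.
    """

    id: str
    frames: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if self.intensities is not None:
            object.__setattr__(
                self, "intensities", np.asarray(self.intensities, dtype=float)
            )
        n = len(frames)
        if n < 2:
            raise ValueError(f"track {self.id!r}: length {n} < 2")
        if positions.ndim != 2 or positions.shape[0] != n:
            raise ValueError(f"track {self.id!r}: positions shape {positions.shape}")
        if positions.shape[1] not in (2, 3):
            raise ValueError(
                f"track {self.id!r}: dimensionality {positions.shape[1]} not in (2, 3)"
            )
        if len(times) != n:
            raise ValueError(f"track {self.id!r}: {len(times)} times for {n} points")
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"track {self.id!r}: times not strictly increasing")
        if not np.all(np.isfinite(positions)):
            raise ValueError(f"track {self.id!r}: non-finite coordinates")
        if self.intensities is not None and len(self.intensities) != n:
            raise ValueError(f"track {self.id!r}: intensity length mismatch")

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Elapsed time in seconds between first and last point."""
        return float(self.times[-1] - self.times[0])


@dataclass
class TrackDataset:
    """Calibrated collection of tracks from one movie.

    ``frame_interval`` is the nominal acquisition interval (s),
    ``pixel_size`` the lateral calibration (μm/px) and ``field_extent``
    the imaged field size per axis (μm).
    """

    tracks: list[Track]
    frame_interval: float
    pixel_size: float = 1.0
    field_extent: tuple[float, ...] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.field_extent is not None and any(e <= 0 for e in self.field_extent):
            raise ValueError("field_extent must be positive")
        dims = {t.ndim for t in self.tracks}
        if len(dims) > 1:
            raise ValueError(f"mixed track dimensionalities: {sorted(dims)}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def ndim(self) -> int:
        if not self.tracks:
            raise ValueError("empty dataset has no dimensionality")
        return self.tracks[0].ndim

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per (track, point)."""
        rows = []
        for t in self.tracks:
            df = pd.DataFrame(
                t.positions, columns=["x", "y", "z"][: t.ndim]
            )
            df.insert(0, "t", t.times)
            df.insert(0, "frame", t.frames)
            df.insert(0, "track_id", t.id)
            if t.intensities is not None:
                df["intensity"] = t.intensities
            rows.append(df)
        if not rows:
            return pd.DataFrame(columns=["track_id", "frame", "t", "x", "y"])
        return pd.concat(rows, ignore_index=True)

    def with_tracks(self, tracks: list[Track]) -> "TrackDataset":
        return replace(self, tracks=list(tracks), metadata=dict(self.metadata))


def _build_tracks(
    grouped: list[tuple[str, pd.DataFrame]], has_z: bool, has_intensity: bool
) -> tuple[list[Track], int]:
    tracks: list[Track] = []
    n_dropped = 0
    cols = ["x", "y", "z"] if has_z else ["x", "y"]
    for tid, g in grouped:
        if len(g) < 2:
            n_dropped += 1
            continue
        tracks.append(
            Track(
                id=str(tid),
                frames=g["frame"].to_numpy(),
                times=g["t"].to_numpy(),
                positions=g[cols].to_numpy(),
                intensities=g["intensity"].to_numpy() if has_intensity else None,
            )
        )
    if n_dropped:
        logger.warning("dropped %d track(s) shorter than 2 points", n_dropped)
    return tracks, n_dropped


# ---------------------------------------------------------------------------
# CSV dialect


def read_tracks_csv(
    path,
    column_map: dict[str, str] | None = None,
    frame_interval: float | None = None,
    pixel_size: float = 1.0,
    position_units: str = "um",
    field_extent: tuple[float, ...] | None = None,
) -> TrackDataset:
    """Read the flat CSV track dialect.

    ``column_map`` maps canonical names (``track_id``, ``frame``, ``t``,
    ``x``, ``y``, ``z``, ``intensity``) to the file's column names. If no
    time column is present, ``frame_interval`` must be given and times are
    ``frame * frame_interval``. With ``position_units="pixel"``,
    coordinates are multiplied by ``pixel_size`` to yield μm.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = {"track_id", "frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise TrackFormatError(f"missing required column(s): {sorted(missing)}")
    dupes = df.duplicated(subset=["track_id", "frame"], keep=False)
    if dupes.any():
        offenders = (
            df.loc[dupes, ["track_id", "frame"]].drop_duplicates().to_records(index=False)
        )
        raise TrackFormatError(f"duplicate (track_id, frame) pairs: {list(offenders)}")
    if "t" not in df.columns:
        if frame_interval is None:
            raise TrackFormatError("no 't' column and no frame_interval supplied")
        df["t"] = df["frame"] * frame_interval
    df = df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)

    has_z = "z" in df.columns
    coord_cols = ["x", "y", "z"] if has_z else ["x", "y"]
    if position_units == "pixel":
        df[coord_cols] = df[coord_cols] * pixel_size
    elif position_units != "um":
        raise ValueError(f"unknown position_units {position_units!r}")

    if frame_interval is None:
        by_track_dt = df.groupby("track_id")["t"].apply(lambda s: np.diff(s).min())
        frame_interval = float(by_track_dt.min())

    tracks, n_dropped = _build_tracks(
        list(df.groupby("track_id", sort=True)), has_z, "intensity" in df.columns
    )
    return TrackDataset(
        tracks=tracks,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        field_extent=field_extent,
        metadata={"source": str(path), "n_dropped": n_dropped},
    )


def write_tracks_csv(ds: TrackDataset, path) -> None:
    """Write a dataset in the flat CSV dialect (μm / seconds)."""
    ds.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TrackMate XML dialect


def read_tracking_xml(path) -> TrackDataset:
    """Read a TrackMate-dialect XML export.

    Spots are taken from ``Model/AllSpots``, track membership from the
    edges under ``Model/AllTracks``. Spatial calibration comes from
    ``Settings/ImageData`` (``pixelwidth``, ``timeinterval``); if the
    model declares pixel spatial units, positions are converted to μm.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise TrackFormatError(f"unparseable XML: {exc}") from exc
    root = tree.getroot()
    model = root.find("Model")
    if model is None:
        raise TrackFormatError("no <Model> element")
    image_data = root.find("Settings/ImageData")
    if image_data is None:
        raise TrackFormatError("missing calibration: no <Settings>/<ImageData> element")
    for attr in ("pixelwidth", "timeinterval"):
        if image_data.get(attr) is None:
            raise TrackFormatError(f"missing calibration attribute: {attr!r}")
    pixel_size = float(image_data.get("pixelwidth"))
    frame_interval = float(image_data.get("timeinterval"))
    width = image_data.get("width")
    height = image_data.get("height")
    field_extent = None
    if width is not None and height is not None:
        field_extent = (float(width) * pixel_size, float(height) * pixel_size)

    spatial_units = (model.get("spatialunits") or "micron").lower()
    scale = pixel_size if spatial_units in ("pixel", "pixels", "px") else 1.0

    spots: dict[str, dict] = {}
    has_z = False
    for spot in model.iterfind("AllSpots/SpotsInFrame/Spot"):
        sid = spot.get("ID")
        rec = {
            "frame": int(float(spot.get("FRAME"))),
            "t": float(spot.get("POSITION_T")),
            "x": float(spot.get("POSITION_X")) * scale,
            "y": float(spot.get("POSITION_Y")) * scale,
        }
        z = spot.get("POSITION_Z")
        if z is not None and float(z) != 0.0:
            has_z = True
        rec["z"] = float(z) * scale if z is not None else 0.0
        intensity = spot.get("MEAN_INTENSITY_CH1") or spot.get("MEAN_INTENSITY")
        rec["intensity"] = float(intensity) if intensity is not None else np.nan
        spots[sid] = rec

    rows = []
    for track in model.iterfind("AllTracks/Track"):
        tid = track.get("TRACK_ID") or track.get("name")
        members: set[str] = set()
        for edge in track.iterfind("Edge"):
            members.add(edge.get("SPOT_SOURCE_ID"))
            members.add(edge.get("SPOT_TARGET_ID"))
        for sid in members:
            if sid not in spots:
                raise TrackFormatError(f"track {tid}: edge references unknown spot {sid}")
            rows.append({"track_id": tid, **spots[sid]})
    if not rows:
        raise TrackFormatError("no tracks found under <AllTracks>")
    df = pd.DataFrame(rows).sort_values(["track_id", "frame"], kind="mergesort")
    has_intensity = df["intensity"].notna().any()
    if not has_z:
        df = df.drop(columns="z")
    tracks, n_dropped = _build_tracks(
        list(df.groupby("track_id", sort=True)), has_z, has_intensity
    )
    return TrackDataset(
        tracks=tracks,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        field_extent=field_extent,
        metadata={"source": str(path), "n_dropped": n_dropped},
    )


def write_trackmate_xml(ds: TrackDataset, path, width_px: int = 512, height_px: int = 512) -> None:
    """Write a dataset as a minimal TrackMate-dialect XML file.

    Intended for building synthetic fixtures and round-trip tests; emits
    only the elements :func:`read_tracking_xml` consumes (spots, track
    edges, image calibration), with positions in μm.
    """
    root = etree.Element("TrackMate", version="7.10.2")
    model = etree.SubElement(root, "Model", spatialunits="micron", timeunits="sec")
    all_spots = etree.SubElement(model, "AllSpots")
    all_tracks = etree.SubElement(model, "AllTracks")
    filtered = etree.SubElement(model, "FilteredTracks")

    frames: dict[int, etree._Element] = {}
    next_id = 0
    for track in ds.tracks:
        spot_ids = []
        for i in range(track.n_points):
            f = int(track.frames[i])
            if f not in frames:
                frames[f] = etree.SubElement(all_spots, "SpotsInFrame", frame=str(f))
            attrs = {
                "ID": str(next_id),
                "FRAME": str(f),
                "POSITION_T": repr(float(track.times[i])),
                "POSITION_X": repr(float(track.positions[i, 0])),
                "POSITION_Y": repr(float(track.positions[i, 1])),
                "POSITION_Z": repr(float(track.positions[i, 2])) if track.ndim == 3 else "0.0",
            }
            if track.intensities is not None:
                attrs["MEAN_INTENSITY_CH1"] = repr(float(track.intensities[i]))
            etree.SubElement(frames[f], "Spot", **attrs)
            spot_ids.append(next_id)
            next_id += 1
        tr = etree.SubElement(all_tracks, "Track", TRACK_ID=str(track.id), name=f"Track_{track.id}")
        for a, b in zip(spot_ids[:-1], spot_ids[1:]):
            etree.SubElement(tr, "Edge", SPOT_SOURCE_ID=str(a), SPOT_TARGET_ID=str(b))
        etree.SubElement(filtered, "TrackID", TRACK_ID=str(track.id))

    settings = etree.SubElement(root, "Settings")
    etree.SubElement(
        settings,
        "ImageData",
        pixelwidth=repr(ds.pixel_size),
        pixelheight=repr(ds.pixel_size),
        timeinterval=repr(ds.frame_interval),
        width=str(width_px),
        height=str(height_px),
    )
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------


def filter_min_duration(ds: TrackDataset, min_duration: float) -> TrackDataset:
    """Keep tracks whose elapsed time exceeds ``min_duration`` (strict >).

    The input dataset is untouched; an empty result is permitted.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    kept = [t for t in ds.tracks if t.duration > min_duration]
    return ds.with_tracks(kept)
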