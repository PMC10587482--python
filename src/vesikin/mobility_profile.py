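"""Mobility-profile classification across vesicle markers.

Per-track features from all markers are pooled, z-scored and embedded
with PCA; each marker's tracks then define a kernel-density "shape" on a
shared PC1/PC2 grid; pairwise L1 ("total") distances between these
normalized shapes form a dissimilarity matrix; and average-linkage
hierarchical clustering cut at k groups classifies the markers into
motion classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

__all__ = [
    "DensityShape",
    "pca_embed",
    "shared_grid",
    "density_shape",
    "total_distance",
    "dissimilarity_matrix",
    "cluster_markers",
]

FEATURE_COLUMNS = ["alpha", "neighbours", "density", "cumdist", "cumtime",
                   "speed", "wide", "fd"]


def synthetic_marker_study(
    seed: int = 0,
    n_tracks: int = 60,
    n_steps: int = 50,
    dt: float = 0.06,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthetic multi-marker study with three generative motion classes.

    Five "diffusive" markers are pure Brownian at D between 0.1 and
    0.3 μm² s⁻¹, two "directed-rich" markers mix 60% directed tracks
    (1–2 μm s⁻¹) with Brownian ones, and one "pure-directed" marker
    emulates a microtubule plus-end reporter. Returns the pooled
    per-track feature table (with a ``marker`` column) and the
    marker → true-class mapping.
    """
    from . import motion_sim, trackstats

    rng = np.random.default_rng(seed)
    duration = n_steps * dt
    spec: list[tuple[str, str, float, float]] = [
        # (marker, class, D, directed_fraction)
        ("diff1", "diffusive", 0.10, 0.0),
        ("diff2", "diffusive", 0.15, 0.0),
        ("diff3", "diffusive", 0.20, 0.0),
        ("diff4", "diffusive", 0.25, 0.0),
        ("diff5", "diffusive", 0.30, 0.0),
        ("mixed1", "directed-rich", 0.20, 0.6),
        ("mixed2", "directed-rich", 0.25, 0.6),
        ("tip", "pure-directed", 0.0, 1.0),
    ]
    tables = []
    truth = {}
    for marker, cls, D, f_dir in spec:
        n_dir = int(round(f_dir * n_tracks))
        parts = []
        if n_tracks - n_dir > 0:
            model = motion_sim.MotionModel(
                D=D, state_set=(motion_sim.BROWNIAN,), dt=dt, duration=duration
            )
            parts.append(motion_sim.simulate_tracks(
                model, n=n_tracks - n_dir, extent=20.0,
                seed=rng.integers(2**31),
            ))
        if n_dir > 0:
            v = rng.uniform(1.0, 2.0)
            model = motion_sim.MotionModel(
                D=0.0, v=v, state_set=(motion_sim.DIRECTED,), dt=dt,
                duration=duration, angular_sigma=0.05,
            )
            parts.append(motion_sim.simulate_tracks(
                model, n=n_dir, extent=20.0, seed=rng.integers(2**31),
            ))
        # truncate to varied lengths so durations spread as in real data
        tracks = []
        for i, t in enumerate(t for ds in parts for t in ds.tracks):
            n_keep = int(rng.integers(max(10, n_steps // 2), n_steps + 1))
            tracks.append(type(t)(
                id=f"{marker}_{i}",
                frames=t.frames[:n_keep + 1],
                times=t.times[:n_keep + 1],
                positions=t.positions[:n_keep + 1],
            ))
        ds = parts[0].with_tracks(tracks)
        table = trackstats.features(ds)
        table["marker"] = marker
        tables.append(table)
        truth[marker] = cls
    return pd.concat(tables, ignore_index=True), truth


@dataclass
class DensityShape:
    """Normalized 2D density of one marker's tracks in PC space.

    ``grid`` is the (2, ny, nx) array of cell-centre coordinates shared
    across markers; ``values`` sum to 1.
    """

    grid: np.ndarray
    values: np.ndarray
    marker: str

    def __post_init__(self) -> None:
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("density values must sum to 1")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")


def pca_embed(
    feature_table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Z-score the pooled per-track feature table and embed with PCA.

    ``feature_table`` needs a ``marker`` column plus the feature columns
    (default: the eight-feature profile). Constant columns are dropped
    with a warning; rows with missing features are rejected. Returns
    (scores with marker labels, loadings, variance-explained fractions).
    """
    cols = feature_columns or FEATURE_COLUMNS
    if "marker" not in feature_table.columns:
        raise ValueError("feature_table needs a 'marker' column")
    if feature_table["marker"].nunique() < 2:
        raise ValueError("need >= 2 markers for a pooled embedding")
    X = feature_table[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in cols if feature_table[c].isna().any()]
        raise ValueError(f"missing values in feature column(s): {bad}")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping constant feature column(s): {dropped}")
        cols = [c for c, k in zip(cols, keep) if k]
        X = X[:, keep]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=min(n_components, Z.shape[1]), svd_solver="full")
    scores = pca.fit_transform(Z)
    # fix sign for determinism: largest-magnitude loading positive
    for j in range(scores.shape[1]):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[j] = -comp
            scores[:, j] = -scores[:, j]
    pc_names = [f"PC{j + 1}" for j in range(scores.shape[1])]
    score_df = pd.DataFrame(scores, columns=pc_names, index=feature_table.index)
    score_df.insert(0, "marker", feature_table["marker"].to_numpy())
    loadings = pd.DataFrame(pca.components_.T, index=cols, columns=pc_names)
    return score_df, loadings, pca.explained_variance_ratio_


def shared_grid(
    scores: pd.DataFrame, grid_size: int = 64, pad_fraction: float = 0.05
) -> np.ndarray:
    """Fixed evaluation lattice over the pooled PC1/PC2 range ± padding."""
    x = scores["PC1"].to_numpy()
    y = scores["PC2"].to_numpy()
    pads = [(x.max() - x.min()) * pad_fraction, (y.max() - y.min()) * pad_fraction]
    gx = np.linspace(x.min() - pads[0], x.max() + pads[0], grid_size)
    gy = np.linspace(y.min() - pads[1], y.max() + pads[1], grid_size)
    return np.stack(np.meshgrid(gx, gy))


def density_shape(
    scores: pd.DataFrame,
    marker: str,
    grid: np.ndarray,
    bandwidth: float | str = "scott",
    min_points: int = 20,
) -> DensityShape:
    """Gaussian-KDE density of one marker's PC1/PC2 points on the grid.

    ``bandwidth`` is a Scott-type factor by default or a fixed KDE factor;
    the evaluated density is renormalized to sum to 1 on the grid.
    """
    pts = scores.loc[scores["marker"] == marker, ["PC1", "PC2"]].to_numpy().T
    if pts.shape[1] < min_points:
        raise ValueError(
            f"marker {marker!r} has {pts.shape[1]} points (< {min_points})"
        )
    kde = gaussian_kde(pts, bw_method=bandwidth)
    values = kde(np.vstack([grid[0].ravel(), grid[1].ravel()])).reshape(grid[0].shape)
    total = values.sum()
    if total <= 0:
        raise ValueError(f"marker {marker!r}: degenerate density")
    return DensityShape(grid=grid, values=values / total, marker=marker)


def total_distance(a: DensityShape, b: DensityShape) -> float:
    """L1 distance Σ|a − b| between two shapes on the same grid ∈ [0, 2]."""
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("shapes were evaluated on different grids")
    return float(np.abs(a.values - b.values).sum())


def dissimilarity_matrix(shapes: list[DensityShape]) -> pd.DataFrame:
    """Symmetric marker × marker total-distance matrix (zero diagonal)."""
    labels = [s.marker for s in shapes]
    n = len(shapes)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = total_distance(shapes[i], shapes[j])
    return pd.DataFrame(m, index=labels, columns=labels)


def cluster_markers(
    dissimilarity: pd.DataFrame, k: int, method: str = "average"
) -> dict:
    """Agglomerative clustering of markers on the dissimilarity matrix.

    Returns the scipy linkage matrix, a marker → group-label Series for
    the k-cut, and the dendrogram leaf order (used to sort heatmaps by
    similarity).
    """
    values = dissimilarity.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if np.any(np.diag(values) != 0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    labels = list(dissimilarity.index)
    if k > len(labels):
        raise ValueError("k cannot exceed the number of markers")
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    leaf_order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return {
        "linkage": Z,
        "labels": pd.Series(flat, index=labels, name="group"),
        "leaf_order": leaf_order,
    }
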