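"""Monitor-network geometry: distances, nearest-within-radius linkage, buffer aggregation.

Two misaligned monitoring networks (PM2.5 mass monitors and the sparser
chemical-speciation monitors) are joined by assigning each target monitor the
values of its closest source monitor within a fixed radius.  Point-level
community data (deaths, population at risk, census covariates at ZIP-code
centroids) are aggregated to each monitor over the same circular buffer.

Distances are great-circle miles on a sphere of radius 3958.8 miles; a planar
mode treats coordinates directly as miles for hand-computable test geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_MILES = 3958.8


@dataclass(frozen=True)
class MonitorLocation:
    """A georeferenced monitoring site."""

    id: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0) or not (-90.0 <= self.lat <= 90.0):
            raise ValueError(
                f"invalid coordinates for {self.id!r}: lon={self.lon}, lat={self.lat}"
            )


@dataclass(frozen=True)
class LinkageResult:
    """Outcome of linking one target monitor to its nearest in-radius source."""

    target_id: str
    source_id: str | None
    distance: float  # miles; NaN when no source within radius


def great_circle_distance(a: MonitorLocation, b: MonitorLocation, *, planar: bool = False) -> float:
    """Distance in miles between two monitors (haversine, or Euclidean if planar)."""
    if planar:
        return float(np.hypot(a.lon - b.lon, a.lat - b.lat))
    return float(
        pairwise_distances(
            np.array([[a.lon, a.lat]]), np.array([[b.lon, b.lat]])
        )[0, 0]
    )


def pairwise_distances(
    coords_a: np.ndarray, coords_b: np.ndarray | None = None, *, planar: bool = False
) -> np.ndarray:
    """All-pairs distance matrix in miles.

    ``coords_*`` are ``(n, 2)`` arrays of (lon, lat) degrees, or of planar mile
    coordinates when ``planar``.  With one argument the matrix is symmetric
    with a zero diagonal.
    """
    a = np.asarray(coords_a, dtype=float)
    b = a if coords_b is None else np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("coordinate arrays must have shape (n, 2)")
    if planar:
        return np.hypot(
            a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1]
        )
    lon_a, lat_a = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon_b, lat_b = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    sin_dlat = np.sin((lat_b - lat_a) / 2.0)
    sin_dlon = np.sin((lon_b - lon_a) / 2.0)
    h = sin_dlat**2 + np.cos(lat_a) * np.cos(lat_b) * sin_dlon**2
    return 2.0 * EARTH_RADIUS_MILES * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def _as_coord_array(monitors: list[MonitorLocation]) -> np.ndarray:
    return np.array([[m.lon, m.lat] for m in monitors], dtype=float).reshape(-1, 2)


def link_nearest_within(
    targets: list[MonitorLocation],
    sources: list[MonitorLocation],
    radius: float,
    *,
    planar: bool = False,
) -> list[LinkageResult]:
    """Link each target to its closest source strictly within ``radius`` miles.

    Equidistant sources tie-break to the lexicographically smallest id.  A
    target with no source in radius links to ``None`` with NaN distance.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not targets:
        return []
    if not sources:
        return [LinkageResult(t.id, None, float("nan")) for t in targets]
    order = sorted(range(len(sources)), key=lambda k: sources[k].id)
    src_sorted = [sources[k] for k in order]
    dist = pairwise_distances(_as_coord_array(targets), _as_coord_array(src_sorted), planar=planar)
    results = []
    for i, t in enumerate(targets):
        j = int(np.argmin(dist[i]))  # first minimum = smallest id among ties
        d = float(dist[i, j])
        if d < radius:
            results.append(LinkageResult(t.id, src_sorted[j].id, d))
        else:
            results.append(LinkageResult(t.id, None, float("nan")))
    return results


def linkage_to_frame(results: list[LinkageResult]) -> pd.DataFrame:
    """Linkage results as a DataFrame with columns target_id, source_id, distance_miles."""
    return pd.DataFrame(
        {
            "target_id": [r.target_id for r in results],
            "source_id": [r.source_id for r in results],
            "distance_miles": [r.distance for r in results],
        }
    )


def aggregate_buffer(
    monitor: MonitorLocation,
    points: list[tuple[MonitorLocation, float]],
    radius: float,
    mode: str = "mean",
    *,
    planar: bool = False,
) -> tuple[float, bool]:
    """Aggregate point values strictly within ``radius`` miles of a monitor.

    Returns ``(value, ok)``; ``ok`` is False (and the value NaN) when no point
    qualifies.  ``mode`` is ``"mean"`` (community covariates) or ``"sum"``
    (deaths and population at risk).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode not in ("mean", "sum"):
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    if points:
        locs = _as_coord_array([p[0] for p in points])
        d = pairwise_distances(np.array([[monitor.lon, monitor.lat]]), locs, planar=planar)[0]
        vals = np.array([p[1] for p in points], dtype=float)[d < radius]
    else:
        vals = np.empty(0)
    if vals.size == 0:
        return float("nan"), False
    return float(vals.mean() if mode == "mean" else vals.sum()), True


def aggregate_all(
    monitors: list[MonitorLocation],
    points: list[tuple[MonitorLocation, float]],
    radius: float,
    mode: str = "mean",
    *,
    assign_to_nearest: bool = False,
    planar: bool = False,
) -> pd.DataFrame:
    """Buffer-aggregate values to every monitor.

    By default a point inside two buffers contributes to both; with
    ``assign_to_nearest`` each point counts only toward its closest monitor.
    """
    if not monitors:
        return pd.DataFrame(columns=["id", "value", "n_points", "ok"])
    rows = []
    if assign_to_nearest and points:
        d = pairwise_distances(
            _as_coord_array([p[0] for p in points]), _as_coord_array(monitors), planar=planar
        )
        owner = np.argmin(d, axis=1)
        for j, m in enumerate(monitors):
            mask = (owner == j) & (d[np.arange(len(points)), owner] < radius)
            vals = np.array([p[1] for p in points], dtype=float)[mask]
            ok = vals.size > 0
            val = float(vals.mean() if mode == "mean" else vals.sum()) if ok else float("nan")
            rows.append((m.id, val, int(vals.size), ok))
    else:
        for m in monitors:
            if points:
                locs = _as_coord_array([p[0] for p in points])
                d = pairwise_distances(np.array([[m.lon, m.lat]]), locs, planar=planar)[0]
                sel = d < radius
            else:
                sel = np.zeros(0, dtype=bool)
            vals = np.array([p[1] for p in points], dtype=float)[sel] if points else np.empty(0)
            ok = vals.size > 0
            val = float(vals.mean() if mode == "mean" else vals.sum()) if ok else float("nan")
            rows.append((m.id, val, int(vals.size), ok))
    return pd.DataFrame(rows, columns=["id", "value", "n_points", "ok"])
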