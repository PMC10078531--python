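"""Movement and habitat covariates.

Home ranges are percent minimum convex polygons (MCPs): at level L the
ceil(L*n) fixes nearest the arithmetic-mean centroid are retained and their
convex hull taken. Intensity of use is total path length divided by the
squared 100% MCP area, computed on a capped post-capture window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon

from .stats import DistanceMatrix, bray_curtis

__all__ = [
    "Track",
    "HomeRange",
    "fit_home_range",
    "centroid_distances",
    "intensity_of_use",
    "habitat_affiliation",
    "structure_profile",
    "structure_dissimilarity",
    "DEFAULT_BIN_EDGES",
]

# (ground tolerance, low/medium edge, medium/high edge) in metres; medium is
# closed on both sides: ground = [0, eps], low = (eps, 0.3), medium = [0.3, 1.6],
# high = (1.6, inf)
DEFAULT_BIN_EDGES = (0.05, 0.3, 1.6)

STRUCTURE_CLASSES = ("ground", "low", "medium", "high")


@dataclass
class Track:
    individual_id: object
    times: np.ndarray  # timestamps, any monotone numeric or datetime64
    xy: np.ndarray  # (n, 2) planar km

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.times = np.asarray(self.times)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        if len(self.times) != len(self.xy):
            raise ValueError("times and xy length mismatch")
        dt = np.diff(self.times.astype("datetime64[s]").astype(float)
                     if np.issubdtype(self.times.dtype, np.datetime64)
                     else self.times.astype(float))
        if (dt <= 0).any():
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.xy)

    def truncate_days(self, window_days: float) -> "Track":
        """Restrict to the first ``window_days`` after the first fix."""
        if np.issubdtype(self.times.dtype, np.datetime64):
            t = self.times.astype("datetime64[s]").astype(float) / 86400.0
        else:
            t = self.times.astype(float)
        keep = t - t[0] <= window_days
        return Track(self.individual_id, self.times[keep], self.xy[keep])

    def path_length(self) -> float:
        """Sum of consecutive-fix step lengths, km."""
        steps = np.diff(self.xy, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


@dataclass
class HomeRange:
    individual_id: object
    mcp95: Polygon
    mcp95_area: float
    mcp100: Polygon
    mcp100_area: float
    centroid: tuple[float, float]
    habitat_affiliation: str | None = None
    floodplain_time_fraction: float | None = None
    structure_profile: pd.Series | None = None
    intensity_of_use: float | None = None


def fit_home_range(track: Track, level: float = 0.95) -> tuple[Polygon, float, tuple[float, float]]:
    """Percent-MCP polygon, its area (km^2), and the track centroid.

    At level L, the ceil(L*n) fixes nearest (Euclidean) to the arithmetic
    mean of all fixes are retained; the polygon is their convex hull. Raises
    on degenerate (collinear or <5) fixes whose hull has zero area.
    """
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    if track.n < 5:
        raise ValueError("need >= 5 fixes for a home range")
    centroid = track.xy.mean(axis=0)
    d = np.hypot(*(track.xy - centroid).T)
    n_keep = int(np.ceil(level * track.n))
    keep = np.argsort(d, kind="stable")[:n_keep]
    hull = MultiPoint([tuple(p) for p in track.xy[keep]]).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        raise ValueError(
            f"degenerate fixes for {track.individual_id!r}: zero-area hull"
        )
    return hull, float(hull.area), (float(centroid[0]), float(centroid[1]))


def build_home_range(track: Track, window_days: float | None = 21.0) -> HomeRange:
    """Fit 95% and 100% MCPs (optionally on a truncated window) plus IU."""
    t = track.truncate_days(window_days) if window_days is not None else track
    mcp95, a95, centroid = fit_home_range(t, 0.95)
    mcp100, a100, _ = fit_home_range(t, 1.0)
    hr = HomeRange(track.individual_id, mcp95, a95, mcp100, a100, centroid)
    hr.intensity_of_use = t.path_length() / a100**2
    return hr


def centroid_distances(ranges: list[HomeRange]) -> DistanceMatrix:
    """Pairwise Euclidean distances (km) between home-range centroids."""
    if len(ranges) < 2:
        raise ValueError("need >= 2 ranges")
    pts = np.array([r.centroid for r in ranges])
    diff = pts[:, None, :] - pts[None, :, :]
    D = np.hypot(diff[..., 0], diff[..., 1])
    return DistanceMatrix([r.individual_id for r in ranges], D)


def intensity_of_use(track: Track, window_days: float | None = 21.0) -> float:
    """Path length / (100% MCP area)^2 on the capped window; units km^-3."""
    t = track.truncate_days(window_days) if window_days is not None else track
    _, area, _ = fit_home_range(t, 1.0)
    if area <= 0:
        raise ValueError("zero-area 100% MCP: intensity of use undefined")
    return t.path_length() / area**2


def habitat_affiliation(
    mcp95: Polygon, floodplain_polygon: Polygon, track: Track
) -> tuple[str, float]:
    """Classify a range as floodplain/woodland and give the time fraction inside.

    Floodplain-affiliated iff the 95% MCP intersects the floodplain polygon
    with positive area. The time fraction is the share of fixes falling
    inside the floodplain polygon (boundary counts as inside).
    """
    if not floodplain_polygon.is_valid or not mcp95.is_valid:
        raise ValueError("invalid polygon")
    overlap = mcp95.intersection(floodplain_polygon)
    affiliated = overlap.area > 0
    inside = sum(
        1 for p in track.xy if floodplain_polygon.covers(Point(p[0], p[1]))
    )
    frac = inside / track.n
    return ("floodplain" if affiliated else "woodland"), float(frac)


def structure_profile(
    heights, bin_edges: tuple[float, float, float] = DEFAULT_BIN_EDGES
) -> pd.Series:
    """Height-class proportions (ground, low, medium, high) of LiDAR points.

    ground = height <= eps; low = (eps, lo); medium = [lo, hi]; high > hi,
    with (eps, lo, hi) = ``bin_edges``. The small eps tolerance resolves the
    overlap between a nominal 0-m ground class and the <lo-m low class.
    """
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        raise ValueError("empty LiDAR point set")
    if (h < 0).any():
        raise ValueError("negative heights")
    eps, lo, hi = bin_edges
    ground = (h <= eps).sum()
    low = ((h > eps) & (h < lo)).sum()
    medium = ((h >= lo) & (h <= hi)).sum()
    high = (h > hi).sum()
    p = np.array([ground, low, medium, high], dtype=float) / h.size
    return pd.Series(p, index=list(STRUCTURE_CLASSES))


def structure_dissimilarity(profiles: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between structure profiles (rows)."""
    if profiles.shape[0] < 2:
        raise ValueError("need >= 2 profiles")
    return bray_curtis(profiles)
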