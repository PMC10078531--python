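"""Synthetic worlds with the statistical structure the analysis assumes.

A world is a rectangular planar landscape (km) split by an x-threshold into
a floodplain strip and woodland. Plant taxa live in habitat pools, have
digestible-protein (DP) values, and spatial kernel mixtures that make
community composition decay smoothly with distance. Individuals carry a
nutritional-condition value that (optionally) increases both their
diet selectivity (a DP-power weighting) and their home-range reversion
strength, so that downstream analyses can recover condition effects on
dietary richness, diet quality, and intensity of use.

All generators are deterministic under a fixed seed; each operation draws
from its own seed stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from ._rng import stream
from .diet_tables import ReadCountTable

__all__ = [
    "PlantTaxon",
    "Landscape",
    "IndividualSpec",
    "OUParams",
    "WorldConfig",
    "SyntheticWorld",
    "make_landscape",
    "make_individuals",
    "simulate_track",
    "simulate_diet_samples",
    "simulate_read_table",
    "simulate_lidar_points",
    "generate_world",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class PlantTaxon:
    taxon_id: str
    habitat_pool: str  # floodplain | woodland | shared
    dp: float  # digestible protein, % dry mass
    kernel_centers: np.ndarray  # (m, 2) planar km
    kernel_bandwidth: float

    def __post_init__(self) -> None:
        if self.dp < 0:
            raise ValueError("dp must be >= 0")
        self.kernel_centers = np.atleast_2d(np.asarray(self.kernel_centers, float))


@dataclass
class Landscape:
    extent: tuple[float, float, float, float]  # (x0, y0, x1, y1) km
    floodplain_boundary: float  # floodplain = x < boundary
    taxa: list[PlantTaxon]
    baseline: float = 1e-6  # ubiquitous background availability per taxon

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def dp_values(self) -> np.ndarray:
        return np.array([t.dp for t in self.taxa])

    @property
    def floodplain_polygon(self) -> Polygon:
        x0, y0, x1, y1 = self.extent
        return box(x0, y0, self.floodplain_boundary, y1)

    def availability(self, x: float, y: float) -> np.ndarray:
        """Normalized relative-abundance vector over taxa at (x, y)."""
        p = np.array([self._taxon_weight(t, x, y) for t in self.taxa])
        total = p.sum()
        if total <= 0:
            raise ValueError(f"zero availability at ({x}, {y})")
        return p / total

    def _taxon_weight(self, t: PlantTaxon, x: float, y: float) -> float:
        if np.isinf(t.kernel_bandwidth):
            return float(len(t.kernel_centers)) + self.baseline
        d2 = ((t.kernel_centers - np.array([x, y])) ** 2).sum(axis=1)
        return float(np.exp(-d2 / (2 * t.kernel_bandwidth**2)).sum()) + self.baseline


@dataclass
class IndividualSpec:
    individual_id: str
    centroid: tuple[float, float]
    condition: float
    reproductive_class: str  # lactating | non-lactating | male
    habitat_affiliation_true: str  # floodplain | woodland
    selectivity: float  # beta(condition) = beta0 + beta1 * condition

    def __post_init__(self) -> None:
        if not np.isfinite(self.condition):
            raise ValueError("condition must be finite")


@dataclass
class OUParams:
    """Discrete mean-reverting walk parameters.

    theta is the per-step reversion fraction toward the centroid, scaled by
    ``exp(theta_condition * condition)`` (clipped to (0, 1]) so that better-
    condition individuals hold tighter ranges and hence show higher
    intensity of use for a comparable path length.
    """

    reversion: float = 0.15
    noise: float = 0.12  # km per step
    theta_condition: float = 0.0

    def theta(self, condition: float) -> float:
        return float(np.clip(self.reversion * np.exp(self.theta_condition * condition), 1e-6, 1.0))


@dataclass
class Track:
    # thin alias re-exported for generator output; analysis uses space_use.Track
    individual_id: str
    times: np.ndarray  # days since first fix
    xy: np.ndarray


# ---------------------------------------------------------------------------
# Landscape & individuals
# ---------------------------------------------------------------------------


def make_landscape(
    n_taxa: int,
    extent: tuple[float, float, float, float] = (0.0, 0.0, 10.0, 10.0),
    floodplain_fraction: float = 0.3,
    bandwidth: float = 2.0,
    dp_params: dict | None = None,
    seed: int = 0,
    pool_fractions: tuple[float, float] = (0.4, 0.4),
    kernels_per_taxon: int = 3,
) -> Landscape:
    """Generate a two-habitat landscape with distance-decaying communities.

    Each taxon's availability field is a Gaussian kernel mixture centered in
    its habitat pool, so Bray-Curtis dissimilarity between sites increases
    with distance in expectation. The floodplain pool's DP distribution has
    a strictly higher mean than the woodland pool's.

    Parameters
    ----------
    n_taxa : int
        Total taxa (>= 2), split into floodplain/woodland/shared pools by
        ``pool_fractions`` (remainder is shared).
    floodplain_fraction : float
        Fraction of the extent's width occupied by the floodplain strip.
    bandwidth : float
        Kernel bandwidth, km; ``np.inf`` yields a homogeneous landscape.
    dp_params : dict
        Keys ``floodplain_mean``, ``woodland_mean``, ``sd``; floodplain mean
        must strictly exceed woodland mean.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("extent must have positive width and height")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if not 0 < floodplain_fraction < 1:
        raise ValueError("floodplain_fraction must lie in (0, 1)")
    dp_params = dict(dp_params or {})
    fp_mean = dp_params.get("floodplain_mean", 24.0)
    wd_mean = dp_params.get("woodland_mean", 14.0)
    dp_sd = dp_params.get("sd", 4.0)
    if fp_mean <= wd_mean:
        raise ValueError("floodplain mean DP must exceed woodland mean DP")

    rng = stream(seed, "make_landscape")
    boundary = x0 + floodplain_fraction * (x1 - x0)

    n_fp = max(1, int(round(pool_fractions[0] * n_taxa)))
    n_wd = max(1, int(round(pool_fractions[1] * n_taxa)))
    n_sh = max(0, n_taxa - n_fp - n_wd)
    pools = ["floodplain"] * n_fp + ["woodland"] * n_wd + ["shared"] * n_sh

    taxa = []
    for i, pool in enumerate(pools):
        if pool == "floodplain":
            cx = rng.uniform(x0, boundary, size=kernels_per_taxon)
            mean_dp = fp_mean
        elif pool == "woodland":
            cx = rng.uniform(boundary, x1, size=kernels_per_taxon)
            mean_dp = wd_mean
        else:
            cx = rng.uniform(x0, x1, size=kernels_per_taxon)
            mean_dp = (fp_mean + wd_mean) / 2
        cy = rng.uniform(y0, y1, size=kernels_per_taxon)
        dp = max(0.5, rng.normal(mean_dp, dp_sd))
        taxa.append(
            PlantTaxon(f"motu_{i:03d}", pool, dp, np.column_stack([cx, cy]), bandwidth)
        )

    # enforce the pool-mean ordering on the realized draws, not just in expectation
    fp_dp = [t.dp for t in taxa if t.habitat_pool == "floodplain"]
    wd_dp = [t.dp for t in taxa if t.habitat_pool == "woodland"]
    gap = np.mean(fp_dp) - np.mean(wd_dp)
    if gap <= 0:
        for t in taxa:
            if t.habitat_pool == "floodplain":
                t.dp += -gap + 1.0
    return Landscape((x0, y0, x1, y1), boundary, taxa)


def make_individuals(
    n: int,
    floodplain_count: int,
    condition_dist=None,
    seed: int = 0,
    landscape: Landscape | None = None,
    beta0: float = 2.0,
    beta1: float = 1.2,
    edge_margin: float = 0.5,
) -> list[IndividualSpec]:
    """Generate individual specs with centroids placed by habitat affiliation.

    Floodplain-affiliated centroids fall within the floodplain strip (or its
    edge); the rest are placed in the woodland. Condition values are i.i.d.
    draws from ``condition_dist`` (a scipy frozen distribution, a constant,
    or None for standard normal). Selectivity is ``beta0 + beta1*condition``.
    """
    if not 0 <= floodplain_count <= n:
        raise ValueError("floodplain_count must lie in [0, n]")
    if landscape is None:
        landscape = make_landscape(10, seed=seed)
    rng = stream(seed, "make_individuals")
    x0, y0, x1, y1 = landscape.extent
    b = landscape.floodplain_boundary
    conditions = _draw_conditions(condition_dist, n, rng)
    classes = rng.choice(["lactating", "non-lactating", "male"], size=n)
    specs = []
    for i in range(n):
        fp = i < floodplain_count
        if fp:
            cx = rng.uniform(x0 + edge_margin, b)
        else:
            cx = rng.uniform(b + edge_margin, x1 - edge_margin)
        cy = rng.uniform(y0 + edge_margin, y1 - edge_margin)
        c = float(conditions[i])
        specs.append(
            IndividualSpec(
                individual_id=f"bb_{i:02d}",
                centroid=(float(cx), float(cy)),
                condition=c,
                reproductive_class=str(classes[i]),
                habitat_affiliation_true="floodplain" if fp else "woodland",
                # clipped at zero: negative exponents would concentrate the diet
                # on low-DP taxa, breaking the monotone condition->richness link
                selectivity=max(0.0, beta0 + beta1 * c),
            )
        )
    return specs


def _draw_conditions(dist, n: int, rng: np.random.Generator) -> np.ndarray:
    if dist is None:
        return rng.standard_normal(n)
    if np.isscalar(dist):
        return np.full(n, float(dist))
    if hasattr(dist, "rvs"):
        return np.asarray(dist.rvs(size=n, random_state=rng), dtype=float)
    raise TypeError("condition_dist must be None, a scalar, or a frozen distribution")


# ---------------------------------------------------------------------------
# Movement
# ---------------------------------------------------------------------------


def simulate_track(
    spec: IndividualSpec,
    n_days: int = 21,
    fixes_per_day: int = 24,
    ou_params: OUParams | None = None,
    seed: int = 0,
) -> Track:
    """Mean-reverting discrete walk around the individual's centroid.

    Produces exactly ``n_days * fixes_per_day`` fixes at regular intervals
    (timestamps in days since first fix). With zero noise every fix sits at
    the centroid and the path length is zero.
    """
    if n_days < 1 or fixes_per_day < 1:
        raise ValueError("n_days and fixes_per_day must be >= 1")
    ou = ou_params or OUParams()
    n = n_days * fixes_per_day
    rng = stream(seed, f"simulate_track:{spec.individual_id}")
    theta = ou.theta(spec.condition)
    mu = np.array(spec.centroid)
    xy = np.empty((n, 2))
    pos = mu.copy()
    for t in range(n):
        xy[t] = pos
        pos = pos + theta * (mu - pos) + ou.noise * rng.standard_normal(2)
    times = np.arange(n) / fixes_per_day
    return Track(spec.individual_id, times, xy)


# ---------------------------------------------------------------------------
# Diet & reads
# ---------------------------------------------------------------------------


def simulate_diet_samples(
    spec: IndividualSpec,
    track: Track,
    landscape: Landscape,
    n_samples: int = 10,
    dirichlet_conc: float = 60.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """True diet proportion vectors for one individual's fecal samples.

    Each sample is taken at a random track fix; expected proportions are
    local availability times ``dp**beta(condition)``, perturbed by Dirichlet
    noise with concentration ``dirichlet_conc`` (``np.inf`` disables noise).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = stream(seed, f"simulate_diet_samples:{spec.individual_id}")
    beta = spec.selectivity
    dp = landscape.dp_values
    out = []
    for _ in range(n_samples):
        fix = track.xy[rng.integers(0, len(track.xy))]
        avail = landscape.availability(fix[0], fix[1])
        with np.errstate(divide="ignore"):
            logw = np.log(avail) + beta * np.log(np.maximum(dp, 1e-300))
        logw[avail <= 0] = -np.inf
        logw -= logw.max()
        w = np.exp(logw)
        total = w.sum()
        if total <= 0:
            raise ValueError("all-zero availability at sampled location")
        p = w / total
        if np.isfinite(dirichlet_conc):
            pos = p > 0
            noisy = np.zeros_like(p)
            noisy[pos] = rng.dirichlet(dirichlet_conc * p[pos])
            p = noisy
        out.append(p)
    return out


def simulate_read_table(
    diet_proportions: dict[str, list[np.ndarray]] | list[np.ndarray],
    n_pcr: int = 3,
    depth_dist=20000,
    contaminant_rate: float = 0.5,
    seed: int = 0,
    taxa: list[str] | None = None,
    n_contaminants: int = 5,
) -> ReadCountTable:
    """Multinomial read counts with PCR replicates and rare contaminants.

    Parameters
    ----------
    diet_proportions : dict or list
        Either ``{individual_id: [proportion vectors]}`` or a bare list (one
        anonymous individual). All vectors share the taxon axis ``taxa``.
    n_pcr : int
        PCR replicates per physical sample; each replicate is an independent
        multinomial draw at its own depth.
    depth_dist : int, tuple, or frozen distribution
        Per-replicate read depth: a constant, a ``(lo, hi)`` uniform-integer
        range, or an object with ``rvs``.
    contaminant_rate : float
        Per-sample inclusion probability of each of ``n_contaminants``
        nuisance mOTUs, each at an expected RRA drawn in [0.1%, 0.9%] — below
        the 1% filter in expectation.
    """
    if n_pcr < 1:
        raise ValueError("n_pcr must be >= 1")
    if not 0 <= contaminant_rate <= 1:
        raise ValueError("contaminant_rate must lie in [0, 1]")
    if isinstance(depth_dist, (int, np.integer)) and depth_dist <= 0:
        raise ValueError("read depth must be positive")
    if isinstance(diet_proportions, (list, tuple)):
        diet_proportions = {"ind_00": list(diet_proportions)}
    n_taxa = len(next(iter(diet_proportions.values()))[0])
    if taxa is None:
        taxa = [f"motu_{i:03d}" for i in range(n_taxa)]
    contam_ids = [f"contam_{j:02d}" for j in range(n_contaminants)]

    rng = stream(seed, "simulate_read_table")
    records = []
    sample_meta = []
    s = 0
    for iid, plist in diet_proportions.items():
        for p in plist:
            sid = f"s{s:04d}"
            s += 1
            sample_meta.append({"sample_id": sid, "individual_id": iid})
            full_p = np.asarray(p, dtype=float)
            ids = list(taxa)
            if contaminant_rate > 0 and n_contaminants > 0:
                include = rng.random(n_contaminants) < contaminant_rate
                c_rra = rng.uniform(0.001, 0.009, size=n_contaminants) * include
                c_tot = c_rra.sum()
                full_p = np.concatenate([full_p * (1 - c_tot), c_rra])
                ids = ids + contam_ids
            full_p = full_p / full_p.sum()
            for rep in range(n_pcr):
                depth = _draw_depth(depth_dist, rng)
                counts = rng.multinomial(depth, full_p)
                nz = np.flatnonzero(counts)
                for t in nz:
                    records.append((sid, rep, ids[t], int(counts[t])))
    reads = pd.DataFrame(records, columns=["sample_id", "pcr_rep", "motu_id", "count"])
    samples = pd.DataFrame(sample_meta)
    return ReadCountTable.from_long(reads, samples)


def _draw_depth(depth_dist, rng) -> int:
    if isinstance(depth_dist, (int, np.integer)):
        d = int(depth_dist)
    elif isinstance(depth_dist, (tuple, list)) and len(depth_dist) == 2:
        d = int(rng.integers(depth_dist[0], depth_dist[1] + 1))
    elif hasattr(depth_dist, "rvs"):
        d = int(depth_dist.rvs(random_state=rng))
    else:
        raise TypeError("depth_dist must be an int, (lo, hi) tuple, or frozen dist")
    if d <= 0:
        raise ValueError("read depth must be positive")
    return d


# ---------------------------------------------------------------------------
# LiDAR
# ---------------------------------------------------------------------------


def simulate_lidar_points(
    landscape: Landscape,
    home_ranges: dict[str, Polygon],
    points_per_range: int = 500,
    seed: int = 0,
    canopy_waves: int = 6,
) -> dict[str, pd.DataFrame]:
    """Per-range LiDAR point clouds (x, y, height) keyed by range id.

    Floodplain-side points come overwhelmingly from the ground/low height
    classes (max height 1.0 m, so the >1.6 m class is empty for treeless
    ranges). Woodland heights follow a spatially autocorrelated canopy
    field, so nearby woodland ranges have more similar structure profiles
    than distant ones in expectation.
    """
    if points_per_range < 4:
        raise ValueError("points_per_range must be >= 4")
    rng = stream(seed, "simulate_lidar_points")
    # smooth canopy field: sum of random plane waves squashed to (0, 1)
    freq = rng.uniform(0.2, 0.8, size=(canopy_waves, 2))
    phase = rng.uniform(0, 2 * np.pi, size=canopy_waves)

    def canopy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        s = np.zeros_like(x)
        for k in range(canopy_waves):
            s += np.cos(freq[k, 0] * x + freq[k, 1] * y + phase[k])
        return 1.0 / (1.0 + np.exp(-s / np.sqrt(canopy_waves)))

    out = {}
    b = landscape.floodplain_boundary
    for rid, poly in home_ranges.items():
        if poly.is_empty or poly.area <= 0:
            raise ValueError(f"empty home range polygon for {rid!r}")
        xs, ys = _sample_in_polygon(poly, points_per_range, rng)
        h = np.empty(points_per_range)
        fp = xs < b
        # floodplain: treeless — ground-heavy, nothing above 1 m
        u = rng.random(points_per_range)
        h[fp & (u < 0.6)] = 0.0
        h[fp & (u >= 0.6) & (u < 0.95)] = rng.uniform(
            0.0, 0.29, size=int((fp & (u >= 0.6) & (u < 0.95)).sum())
        )
        h[fp & (u >= 0.95)] = rng.uniform(0.3, 1.0, size=int((fp & (u >= 0.95)).sum()))
        # woodland: canopy-field-driven mixture including medium/high
        wd = ~fp
        c = canopy(xs[wd], ys[wd])
        uw = rng.random(wd.sum())
        p_high = 0.10 + 0.55 * c
        p_med = 0.25
        hw = np.where(
            uw < p_high,
            rng.uniform(1.61, 8.0, size=wd.sum()),
            np.where(
                uw < p_high + p_med,
                rng.uniform(0.3, 1.6, size=wd.sum()),
                np.where(
                    uw < p_high + p_med + 0.2,
                    rng.uniform(0.0, 0.29, size=wd.sum()),
                    0.0,
                ),
            ),
        )
        h[wd] = hw
        out[rid] = pd.DataFrame({"x": xs, "y": ys, "height": h})
    return out


def _sample_in_polygon(poly: Polygon, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    from shapely.geometry import Point

    x0, y0, x1, y1 = poly.bounds
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        cx = rng.uniform(x0, x1, size=m)
        cy = rng.uniform(y0, y1, size=m)
        inside = np.fromiter(
            (poly.covers(Point(a, b)) for a, b in zip(cx, cy)), bool, count=m
        )
        take = min(inside.sum(), n - got)
        xs[got : got + take] = cx[inside][:take]
        ys[got : got + take] = cy[inside][:take]
        got += take
    return xs, ys


# ---------------------------------------------------------------------------
# Whole-world convenience
# ---------------------------------------------------------------------------


@dataclass
class WorldConfig:
    n_individuals: int = 15
    floodplain_count: int = 7
    n_taxa: int = 60
    extent: tuple[float, float, float, float] = (0.0, 0.0, 10.0, 10.0)
    floodplain_fraction: float = 0.3
    bandwidth: float = 2.0
    dp_params: dict = field(
        default_factory=lambda: {"floodplain_mean": 24.0, "woodland_mean": 14.0, "sd": 6.0}
    )
    beta0: float = 2.0
    beta1: float = 1.2  # condition -> selectivity slope (0 switches the effect off)
    min_samples: int = 6
    max_samples: int = 14
    n_days: int = 42
    fixes_per_day: int = 24
    ou: OUParams = field(default_factory=lambda: OUParams(0.15, 0.12, 0.5))
    dirichlet_conc: float = 40.0
    n_pcr: int = 3
    depth_range: tuple[int, int] = (9000, 30000)
    contaminant_rate: float = 0.5
    n_contaminants: int = 5
    lidar_points_per_range: int = 400


@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    landscape: Landscape
    individuals: list[IndividualSpec]
    tracks: dict[str, Track]
    true_diets: dict[str, list[np.ndarray]]
    read_table: ReadCountTable
    traits: pd.Series  # taxon -> DP (% dry mass)

    def truth(self) -> dict:
        return {
            "seed": self.seed,
            "n_individuals": self.config.n_individuals,
            "floodplain_count": self.config.floodplain_count,
            "beta0": self.config.beta0,
            "beta1": self.config.beta1,
            "theta_condition": self.config.ou.theta_condition,
            "condition": {s.individual_id: s.condition for s in self.individuals},
            "habitat": {
                s.individual_id: s.habitat_affiliation_true for s in self.individuals
            },
        }


def generate_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate a complete synthetic study: landscape, animals, GPS, reads."""
    cfg = config or WorldConfig()
    land = make_landscape(
        cfg.n_taxa,
        extent=cfg.extent,
        floodplain_fraction=cfg.floodplain_fraction,
        bandwidth=cfg.bandwidth,
        dp_params=cfg.dp_params,
        seed=seed,
    )
    specs = make_individuals(
        cfg.n_individuals,
        cfg.floodplain_count,
        seed=seed,
        landscape=land,
        beta0=cfg.beta0,
        beta1=cfg.beta1,
    )
    rng = stream(seed, "generate_world")
    tracks = {}
    diets = {}
    for s in specs:
        tracks[s.individual_id] = simulate_track(
            s, cfg.n_days, cfg.fixes_per_day, cfg.ou, seed=seed
        )
        n_samp = int(rng.integers(cfg.min_samples, cfg.max_samples + 1))
        diets[s.individual_id] = simulate_diet_samples(
            s, tracks[s.individual_id], land, n_samp, cfg.dirichlet_conc, seed=seed
        )
    table = simulate_read_table(
        diets,
        n_pcr=cfg.n_pcr,
        depth_dist=cfg.depth_range,
        contaminant_rate=cfg.contaminant_rate,
        seed=seed,
        taxa=land.taxon_ids,
        n_contaminants=cfg.n_contaminants,
    )
    traits = pd.Series(land.dp_values, index=land.taxon_ids, name="dp_percent")
    return SyntheticWorld(cfg, seed, land, specs, tracks, diets, table, traits)
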