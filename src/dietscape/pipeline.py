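"""End-to-end analysis orchestration.

Composes diet_tables -> diet_metrics -> space_use -> stats into one result
bundle: population and per-habitat perMANOVAs with pairwise contrasts,
Mantel distance-decay tests, condition regressions with AICc ranking, the
single-sample versus longitudinal comparison, and species-accumulation
curves.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box, mapping, shape

from . import diet_metrics as dm
from . import diet_tables as dt
from . import space_use as su
from . import stats as st
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "Dataset", "ResultBundle", "run_pipeline", "report"]

AICC_MODEL_SET = (
    "condition",
    "condition + habitat",
    "condition + lactation",
    "condition + habitat + lactation",
    "habitat",
    "lactation",
    "habitat + lactation",
)

_CONFIG_FIELDS = {
    "depth": (int, lambda v: v > 0),
    "rra_filter": (float, lambda v: 0 <= v < 1),
    "k": (int, lambda v: v >= 1),
    "B": (int, lambda v: v >= 1),
    "n_perm": (int, lambda v: v >= 1),
    "n_perm_pairwise": (int, lambda v: v >= 1),
    "window_days": (float, lambda v: v > 0),
    "mcp_level": (float, lambda v: 0 < v <= 1),
    "lidar_bin_edges": (tuple, lambda v: 0 < v[0] < v[1] < v[2]),
    "seed": (int, lambda v: True),
    "exclude_samples": (list, lambda v: True),
    "filter_before_rarefaction": (bool, lambda v: True),
}


@dataclass
class AnalysisConfig:
    """Pipeline parameters; defaults follow the study protocol."""

    depth: int = 7000
    rra_filter: float = 0.01
    k: int = 6
    B: int = 1000
    n_perm: int = 9999
    n_perm_pairwise: int = 9999
    window_days: float = 21.0
    mcp_level: float = 0.95
    lidar_bin_edges: tuple = su.DEFAULT_BIN_EDGES
    seed: int = 0
    exclude_samples: list = field(default_factory=list)
    filter_before_rarefaction: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        unknown = set(d) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, raw in d.items():
            typ, check = _CONFIG_FIELDS[key]
            val = typ(raw) if typ is not tuple else tuple(raw)
            if not check(val):
                raise ValueError(f"config key {key!r}: value {raw!r} out of range")
            kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)


@dataclass
class Dataset:
    """Everything the analysis consumes, habitat polygon included."""

    reads: dt.ReadCountTable
    gps: pd.DataFrame  # individual_id, t_days, x_km, y_km
    traits: pd.Series  # motu_id -> DP percent
    animals: pd.DataFrame  # indexed by individual_id: condition, reproductive_class
    floodplain: Polygon
    lidar: pd.DataFrame | None = None  # x, y, height (global cloud)
    lidar_by_range: dict | None = None  # individual_id -> DataFrame(x, y, height)
    year: pd.Series | None = None  # sample_id -> year (perMANOVA block)

    @classmethod
    def from_world(cls, world: syn.SyntheticWorld, lidar_seed: int | None = None) -> "Dataset":
        gps_rows = []
        for iid, tr in world.tracks.items():
            for t, (x, y) in zip(tr.times, tr.xy):
                gps_rows.append((iid, float(t), float(x), float(y)))
        gps = pd.DataFrame(gps_rows, columns=["individual_id", "t_days", "x_km", "y_km"])
        animals = pd.DataFrame(
            {
                "condition": {s.individual_id: s.condition for s in world.individuals},
                "reproductive_class": {
                    s.individual_id: s.reproductive_class for s in world.individuals
                },
            }
        )
        # per-range LiDAR clouds, simulated inside each individual's 95% MCP
        ranges = {}
        for iid, tr in world.tracks.items():
            track = su.Track(iid, tr.times, tr.xy)
            poly, _, _ = su.fit_home_range(track.truncate_days(21.0), 0.95)
            ranges[iid] = poly
        lidar_by_range = syn.simulate_lidar_points(
            world.landscape,
            ranges,
            points_per_range=world.config.lidar_points_per_range,
            seed=world.seed if lidar_seed is None else lidar_seed,
        )
        return cls(
            reads=world.read_table,
            gps=gps,
            traits=world.traits,
            animals=animals,
            floodplain=world.landscape.floodplain_polygon,
            lidar_by_range=lidar_by_range,
        )

    @classmethod
    def from_dir(cls, data_dir) -> "Dataset":
        """Load the CSV/GeoJSON dialect written by ``dietscape simulate``."""
        d = Path(data_dir)
        reads = pd.read_csv(d / "reads.csv")
        animals = pd.read_csv(d / "animals.csv").set_index("individual_id")
        samples = reads[["sample_id"]].drop_duplicates()
        sample_map = pd.read_csv(d / "samples.csv") if (d / "samples.csv").exists() else None
        if sample_map is None:
            raise FileNotFoundError("samples.csv (sample_id -> individual_id) required")
        table = dt.ReadCountTable.from_long(reads, sample_map)
        gps = pd.read_csv(d / "gps.csv")
        traits = pd.read_csv(d / "traits.csv").set_index("motu_id")["dp_percent"]
        lidar = pd.read_csv(d / "lidar.csv") if (d / "lidar.csv").exists() else None
        if lidar is not None:
            lidar = lidar.rename(columns={"x_km": "x", "y_km": "y", "height_m": "height"})
        with open(d / "floodplain.geojson") as fh:
            floodplain = shape(json.load(fh)["geometry"])
        year = None
        if "year" in sample_map.columns:
            year = sample_map.set_index("sample_id")["year"]
        return cls(
            reads=table, gps=gps, traits=traits, animals=animals,
            floodplain=floodplain, lidar=lidar, year=year,
        )


@dataclass
class ResultBundle:
    params: dict
    space: pd.DataFrame
    structure: pd.DataFrame
    richness: pd.DataFrame
    population_richness: tuple
    quality: pd.DataFrame
    permanova: dict
    pairwise: pd.DataFrame
    mantel: dict
    nmds_stress: float
    ols: dict
    aicc: pd.DataFrame
    welch_single_vs_longitudinal: dict
    accumulation: pd.DataFrame

    def to_json_dict(self) -> dict:
        return _jsonify(dataclasses.asdict(self))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def _permanova_dict(res: st.PermanovaResult) -> dict:
    t = res.term("factor")
    return {
        "pseudo_f": t.pseudo_f,
        "df": [t.df, res.residual_df],
        "r2": t.r2,
        "p": t.p_perm,
        "n_perm": res.n_perm,
        "total_ss": res.total_ss,
    }


def run_pipeline(dataset: Dataset, config: AnalysisConfig | None = None) -> ResultBundle:
    """Run the full analysis on a dataset; deterministic under config.seed."""
    cfg = config or AnalysisConfig()
    seed = cfg.seed

    # --- diet tables ------------------------------------------------------
    profiles = dt.process_reads(
        dataset.reads,
        threshold=cfg.rra_filter,
        depth=cfg.depth,
        seed=seed,
        filter_before_rarefaction=cfg.filter_before_rarefaction,
    )
    profiles = [p for p in profiles if p.sample_id not in set(cfg.exclude_samples)]
    if not profiles:
        raise RuntimeError("diet_tables stage: no samples survived processing")
    sample_to_ind = dataset.reads.samples["individual_id"]
    by_ind: dict = {}
    for p in profiles:
        by_ind.setdefault(sample_to_ind.loc[p.sample_id], []).append(p)

    # --- space use --------------------------------------------------------
    tracks = {}
    for iid, g in dataset.gps.groupby("individual_id"):
        g = g.sort_values("t_days")
        tracks[iid] = su.Track(iid, g["t_days"].to_numpy(), g[["x_km", "y_km"]].to_numpy())
    ranges = {}
    space_rows = []
    for iid, track in tracks.items():
        hr = su.build_home_range(track, window_days=cfg.window_days)
        habitat, frac = su.habitat_affiliation(hr.mcp95, dataset.floodplain, track)
        hr.habitat_affiliation = habitat
        hr.floodplain_time_fraction = frac
        ranges[iid] = hr
        space_rows.append(
            {
                "individual_id": iid,
                "mcp95_km2": hr.mcp95_area,
                "mcp100_km2": hr.mcp100_area,
                "iu": hr.intensity_of_use,
                "habitat": habitat,
                "floodplain_fraction": frac,
                "centroid_x": hr.centroid[0],
                "centroid_y": hr.centroid[1],
            }
        )
    space = pd.DataFrame(space_rows).set_index("individual_id")

    structure_rows = {}
    for iid, hr in ranges.items():
        if dataset.lidar_by_range is not None and iid in dataset.lidar_by_range:
            heights = dataset.lidar_by_range[iid]["height"].to_numpy()
        elif dataset.lidar is not None:
            from shapely.geometry import Point

            pts = dataset.lidar
            inside = pts.apply(
                lambda r: hr.mcp95.covers(Point(r["x"], r["y"])), axis=1
            )
            heights = pts.loc[inside, "height"].to_numpy()
        else:
            heights = None
        if heights is not None and heights.size:
            structure_rows[iid] = su.structure_profile(heights, cfg.lidar_bin_edges)
    structure = pd.DataFrame(structure_rows).T

    # --- diet metrics -----------------------------------------------------
    standardized = {}
    richness_rows = []
    for iid, profs in by_ind.items():
        if len(profs) < cfg.k:
            logger.warning("excluding %s: %d samples < k=%d", iid, len(profs), cfg.k)
            continue
        sd = dm.standardize_diet(profs, individual_id=iid, k=cfg.k, B=cfg.B, seed=seed)
        standardized[iid] = sd
        mean, sdev = dm.dietary_richness(sd)
        single = dm.single_sample_richness(profs, B=cfg.B, seed=seed)
        richness_rows.append(
            {
                "individual_id": iid,
                "richness_mean": mean,
                "richness_sd": sdev,
                "single_sample_mean": single,
                "n_samples": len(profs),
            }
        )
    if not standardized:
        raise RuntimeError("diet_metrics stage: no individual passes the >=k filter")
    richness = pd.DataFrame(richness_rows).set_index("individual_id")
    pop_rich = dm.population_richness(
        {i: p for i, p in by_ind.items() if len(p) >= cfg.k}, k=cfg.k, B=cfg.B, seed=seed
    )

    quality_rows = []
    for iid, sd in standardized.items():
        q = dm.diet_quality_dp(sd, dataset.traits)
        quality_rows.append(
            {"individual_id": iid, "dp_weighted": q.dp_weighted, "coverage": q.coverage}
        )
    quality = pd.DataFrame(quality_rows).set_index("individual_id")

    accum_rows = []
    for iid, profs in by_ind.items():
        if len(profs) < 2:
            continue
        curve = dm.species_accumulation(profs)
        curve.insert(0, "individual_id", iid)
        accum_rows.append(curve)
    accumulation = pd.concat(accum_rows, ignore_index=True)

    # --- sample-level composition tests ----------------------------------
    kept = [p for p in profiles if sample_to_ind.loc[p.sample_id] in standardized]
    rra = dt.profiles_to_frame(kept)
    sample_ind = np.array([sample_to_ind.loc[p.sample_id] for p in kept])
    D_samples = st.bray_curtis(rra)
    block = None
    if dataset.year is not None:
        block = dataset.year.reindex([p.sample_id for p in kept]).to_numpy()

    permanova_out = {
        "population": _permanova_dict(
            st.permanova(D_samples, sample_ind, block=block, n_perm=cfg.n_perm, seed=seed)
        )
    }
    habitat_of = space["habitat"]
    for habitat in ("woodland", "floodplain"):
        mask = np.array([habitat_of.get(i) == habitat for i in sample_ind])
        ids = np.unique(sample_ind[mask])
        if ids.size >= 2 and all((sample_ind[mask] == i).sum() >= 2 for i in ids):
            sub_block = block[mask] if block is not None else None
            if sub_block is not None and np.unique(sub_block).size < 2:
                sub_block = None
            permanova_out[habitat] = _permanova_dict(
                st.permanova(
                    D_samples.subset(mask), sample_ind[mask], block=sub_block,
                    n_perm=cfg.n_perm, seed=seed,
                )
            )
        else:
            permanova_out[habitat] = None

    contrasts = st.pairwise_permanova(
        D_samples, sample_ind, block=block, n_perm=cfg.n_perm_pairwise, seed=seed
    )
    pairwise = pd.DataFrame(
        [
            {
                "level_a": c.level_a,
                "level_b": c.level_b,
                "pseudo_f": c.pseudo_f,
                "r2": c.r2,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
            }
            for c in contrasts
        ]
    )

    nmds_res = st.nmds(D_samples, k=2, seed=seed)

    # --- individual-level distance-decay ---------------------------------
    ind_ids = sorted(standardized)
    std_rra = pd.DataFrame({i: standardized[i].mean_rra for i in ind_ids}).T.fillna(0.0)
    D_diet = st.bray_curtis(std_rra)
    hr_list = [ranges[i] for i in ind_ids]
    D_cent = su.centroid_distances(hr_list)
    D_struct = None
    if not structure.empty and set(ind_ids) <= set(structure.index):
        D_struct = su.structure_dissimilarity(structure.loc[ind_ids])

    mantel_out: dict = {}
    scales = {
        "population": ind_ids,
        "woodland": [i for i in ind_ids if habitat_of.get(i) == "woodland"],
        "floodplain": [i for i in ind_ids if habitat_of.get(i) == "floodplain"],
    }
    for scale, ids in scales.items():
        entry: dict = {}
        if len(ids) >= 4:
            sel = np.array([ind_ids.index(i) for i in ids])
            d1 = D_diet.subset(sel)
            entry["centroid"] = dataclasses.asdict(
                st.mantel(d1, D_cent.subset(sel), n_perm=cfg.n_perm, seed=seed)
            )
            if D_struct is not None:
                entry["structure"] = dataclasses.asdict(
                    st.mantel(d1, D_struct.subset(sel), n_perm=cfg.n_perm, seed=seed)
                )
        else:
            entry = {"not_applicable": True}
        mantel_out[scale] = entry

    # --- condition regressions -------------------------------------------
    cond = dataset.animals["condition"]
    frame = pd.DataFrame(
        {
            "condition": cond.reindex(ind_ids),
            "iu": space["iu"].reindex(ind_ids),
            "dp": quality["dp_weighted"].reindex(ind_ids),
            "richness": richness["richness_mean"].reindex(ind_ids),
            "habitat": habitat_of.reindex(ind_ids),
            "lactation": dataset.animals["reproductive_class"].reindex(ind_ids),
        }
    )
    ols_out: dict = {}
    for scale, ids in scales.items():
        sub = frame.loc[[i for i in ids if i in frame.index]].dropna(subset=["condition"])
        entry = {}
        for resp in ("iu", "dp", "richness"):
            if len(sub) >= 3 and sub[resp].notna().all():
                fit = st.ols_fit(sub[resp], sub[["condition"]], term_names=["condition"])
                entry[resp] = {
                    "slope": float(fit.params[1]),
                    "p": float(fit.pvalues[1]),
                    "r2": fit.r2,
                    "n": fit.n,
                }
            else:
                entry[resp] = None
        ols_out[scale] = entry

    aicc = _aicc_table(frame)

    welch = dataclasses.asdict(
        st.welch_t(richness["single_sample_mean"], richness["richness_mean"])
    )
    welch["mean_single"] = float(richness["single_sample_mean"].mean())
    welch["mean_longitudinal"] = float(richness["richness_mean"].mean())

    return ResultBundle(
        params=dataclasses.asdict(cfg),
        space=space,
        structure=structure,
        richness=richness,
        population_richness=pop_rich,
        quality=quality,
        permanova=permanova_out,
        pairwise=pairwise,
        mantel=mantel_out,
        nmds_stress=nmds_res.stress,
        ols=ols_out,
        aicc=aicc,
        welch_single_vs_longitudinal=welch,
        accumulation=accumulation,
    )


def _design(frame: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = []
    names = []
    for t in terms:
        if t == "condition":
            cols.append(frame["condition"].to_numpy(float)[:, None])
            names.append("condition")
        else:
            dummies = pd.get_dummies(frame[t], prefix=t, drop_first=True)
            cols.append(dummies.to_numpy(float))
            names.extend(dummies.columns.tolist())
    return np.hstack(cols), names


def _aicc_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Seven-model AICc comparison for dietary richness."""
    sub = frame.dropna()
    n = len(sub)
    y = sub["richness"].to_numpy(float)
    fits = []
    for label in AICC_MODEL_SET:
        terms = [t.strip() for t in label.split("+")]
        try:
            X, names = _design(sub, terms)
            fits.append((label, st.ols_fit(y, X, term_names=names)))
        except ValueError as exc:
            logger.warning("AICc model %r skipped: %s", label, exc)
    if not fits:
        logger.warning("AICc table empty: too few individuals for any model")
        return pd.DataFrame(columns=["model", "k", "adj_r2", "delta_aicc", "weight"])
    try:
        rank = st.aicc_rank(fits, n)
    except ValueError as exc:
        logger.warning("AICc ranking skipped: %s", exc)
        return pd.DataFrame(columns=["model", "k", "adj_r2", "delta_aicc", "weight"])
    return pd.DataFrame(
        [
            {
                "model": m.label,
                "k": m.k,
                "adj_r2": m.adj_r2,
                "delta_aicc": m.delta_aicc,
                "weight": m.weight,
            }
            for m in rank.models
        ]
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report(bundle: ResultBundle) -> tuple[str, dict]:
    """Render a bundle as (markdown summary, JSON-ready dict)."""
    required = [
        "permanova", "pairwise", "mantel", "ols", "aicc",
        "welch_single_vs_longitudinal", "richness",
    ]
    missing = [r for r in required if getattr(bundle, r, None) is None]
    if missing:
        raise ValueError(f"incomplete bundle, missing sections: {missing}")
    js = bundle.to_json_dict()
    lines = ["# Diet variation analysis", ""]
    pop = bundle.permanova["population"]
    lines.append(
        f"Population perMANOVA (individual ID): pseudo-F({pop['df'][0]}, {pop['df'][1]}) "
        f"= {pop['pseudo_f']:.2f}, R2 = {pop['r2']:.2f}, p = {pop['p']:.4g} "
        f"({pop['n_perm']} permutations)"
    )
    for habitat in ("woodland", "floodplain"):
        h = bundle.permanova.get(habitat)
        if h is None:
            lines.append(f"{habitat.capitalize()} perMANOVA: not applicable")
        else:
            lines.append(
                f"{habitat.capitalize()} perMANOVA: pseudo-F({h['df'][0]}, {h['df'][1]}) "
                f"= {h['pseudo_f']:.2f}, R2 = {h['r2']:.2f}, p = {h['p']:.4g}"
            )
    n_sig = int((bundle.pairwise["p_adjusted"] < 0.05).sum())
    lines.append(
        f"Pairwise contrasts: {n_sig} of {len(bundle.pairwise)} significant after Holm"
    )
    lines.append("")
    lines.append("## Distance decay (Mantel)")
    for scale, entry in bundle.mantel.items():
        if entry.get("not_applicable"):
            lines.append(f"- {scale}: not applicable")
            continue
        for kind, res in entry.items():
            lines.append(
                f"- {scale}/{kind}: r = {res['r']:.3f}, p = {res['p_perm']:.4g}"
            )
    lines.append("")
    lines.append("## Condition regressions")
    for scale, entry in bundle.ols.items():
        for resp, res in entry.items():
            if res is None:
                lines.append(f"- {scale}/{resp}: not applicable")
            else:
                lines.append(
                    f"- {scale}/{resp}: slope = {res['slope']:.3g}, "
                    f"p = {res['p']:.3g}, R2 = {res['r2']:.2f} (n = {res['n']})"
                )
    lines.append("")
    lines.append("## Richness")
    pr = bundle.population_richness
    lines.append(f"- population: {pr[0]:.1f} +/- {pr[1]:.2f} taxa")
    lines.append(
        f"- individuals: mean {bundle.richness['richness_mean'].mean():.1f} taxa"
    )
    w = bundle.welch_single_vs_longitudinal
    lines.append(
        f"- single vs longitudinal: {w['mean_single']:.1f} vs "
        f"{w['mean_longitudinal']:.1f} taxa (Welch t = {w['t']:.2f}, p = {w['p']:.3g})"
    )
    lines.append("")
    lines.append("## AICc model ranking (richness)")
    for _, row in bundle.aicc.iterrows():
        lines.append(
            f"- {row['model']}: dAICc = {row['delta_aicc']:.3f}, "
            f"w = {row['weight']:.3f}, adj-R2 = {row['adj_r2']:.2f}"
        )
    return "\n".join(lines) + "\n", js


def write_world(world: syn.SyntheticWorld, out_dir, dataset: Dataset | None = None) -> None:
    """Write a synthetic world to the documented CSV/GeoJSON dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = dataset or Dataset.from_world(world)
    counts = ds.reads.counts.stack()
    counts = counts[counts > 0].rename("count").reset_index()
    counts.columns = ["sample_id", "pcr_rep", "motu_id", "count"]
    counts.to_csv(out / "reads.csv", index=False)
    ds.reads.samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        out / "samples.csv", index=False
    )
    ds.gps.to_csv(out / "gps.csv", index=False)
    ds.traits.rename_axis("motu_id").reset_index().to_csv(out / "traits.csv", index=False)
    ds.animals.rename_axis("individual_id").reset_index().to_csv(
        out / "animals.csv", index=False
    )
    if ds.lidar_by_range:
        cloud = pd.concat(ds.lidar_by_range.values(), ignore_index=True)
        cloud.rename(columns={"x": "x_km", "y": "y_km", "height": "height_m"}).to_csv(
            out / "lidar.csv", index=False
        )
    with open(out / "floodplain.geojson", "w") as fh:
        json.dump(
            {"type": "Feature", "properties": {}, "geometry": mapping(ds.floodplain)},
            fh,
        )
    with open(out / "truth.json", "w") as fh:
        json.dump(_jsonify(world.truth()), fh, indent=2)
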