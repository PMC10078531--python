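"""Individual-level diet summarization.

The analysis unit is the bootstrap-standardized diet: repeated subsamples of
k fecal samples per individual, averaged into one RRA vector per individual,
with per-iteration taxon counts retained for richness statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from ._rng import stream
from .diet_tables import DietProfile

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizedDiet",
    "DietQuality",
    "standardize_diet",
    "dietary_richness",
    "population_richness",
    "shannon_diversity",
    "species_accumulation",
    "diet_quality_dp",
    "single_sample_richness",
]


@dataclass
class StandardizedDiet:
    individual_id: object
    mean_rra: pd.Series
    richness_draws: np.ndarray
    n_samples_available: int
    k: int
    B: int
    seed: int


@dataclass
class DietQuality:
    individual_id: object
    dp_weighted: float
    coverage: float


def _profile_matrix(profiles: list[DietProfile]) -> pd.DataFrame:
    M = pd.DataFrame({p.sample_id: p.rra for p in profiles}).T.fillna(0.0)
    return M


def standardize_diet(
    profiles: list[DietProfile],
    individual_id=None,
    k: int = 6,
    B: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> StandardizedDiet:
    """Bootstrap-standardize one individual's diet to ``k`` samples.

    Each of ``B`` iterations draws ``k`` of the individual's samples (without
    replacement by default), averages their RRA vectors, and records the
    taxon count of that iteration's mean. ``mean_rra`` is the across-iteration
    mean, renormalized to sum to one.

    Raises
    ------
    ValueError
        If the individual has fewer than ``k`` samples (such individuals are
        excluded from individual-level analyses).
    """
    n = len(profiles)
    if n < k:
        raise ValueError(
            f"individual {individual_id!r}: {n} samples < k={k}; excluded"
        )
    M = _profile_matrix(profiles).to_numpy()
    taxa = _profile_matrix(profiles).columns
    rng = stream(seed, "standardize_diet")
    mean_accum = np.zeros(M.shape[1])
    richness = np.empty(B, dtype=int)
    for b in range(B):
        idx = rng.choice(n, size=k, replace=replace)
        it_mean = M[idx].mean(axis=0)
        richness[b] = int((it_mean > 0).sum())
        mean_accum += it_mean
    mean_rra = mean_accum / B
    total = mean_rra.sum()
    if total > 0:
        mean_rra = mean_rra / total
    return StandardizedDiet(
        individual_id=individual_id,
        mean_rra=pd.Series(mean_rra, index=taxa),
        richness_draws=richness,
        n_samples_available=n,
        k=k,
        B=B,
        seed=seed,
    )


def dietary_richness(sd: StandardizedDiet) -> tuple[float, float]:
    """Mean and SD of the per-iteration taxon counts."""
    return float(sd.richness_draws.mean()), float(sd.richness_draws.std(ddof=1))


def population_richness(
    profiles_by_individual: dict, k: int = 6, B: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Mean and SD across iterations of the union taxon count over individuals.

    In each iteration every qualifying individual (>= k samples) contributes
    the union of taxa in a fresh draw of k samples; the iteration's statistic
    is the size of the union over individuals.
    """
    mats = []
    for iid, profs in profiles_by_individual.items():
        if len(profs) < k:
            logger.warning("excluding %s: %d samples < k=%d", iid, len(profs), k)
            continue
        M = _profile_matrix(profs)
        mats.append((iid, M))
    if not mats:
        raise ValueError("no individual passes the minimum-samples filter")
    all_taxa = sorted(set().union(*(set(M.columns) for _, M in mats)))
    taxa_pos = {t: i for i, t in enumerate(all_taxa)}
    draws = np.empty(B)
    rngs = {iid: stream(seed, f"population_richness:{iid}") for iid, _ in mats}
    occ = {}
    cols = {}
    for iid, M in mats:
        occ[iid] = (M.to_numpy() > 0)
        cols[iid] = np.array([taxa_pos[t] for t in M.columns])
    for b in range(B):
        union = np.zeros(len(all_taxa), dtype=bool)
        for iid, M in mats:
            n = occ[iid].shape[0]
            idx = rngs[iid].choice(n, size=k, replace=False)
            present = occ[iid][idx].any(axis=0)
            union[cols[iid][present]] = True
        draws[b] = union.sum()
    return float(draws.mean()), float(draws.std(ddof=1))


def shannon_diversity(sd: StandardizedDiet, B: int | None = None, profiles=None) -> float:
    """Mean Shannon index over bootstrap iterations.

    Recomputes the iteration draws from the stored seed so the index is
    averaged over the same resampling distribution as richness. Falls back
    to the Shannon index of ``mean_rra`` when the source profiles are not
    supplied.
    """
    if profiles is None:
        p = sd.mean_rra.to_numpy()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())
    M = _profile_matrix(profiles).to_numpy()
    n = M.shape[0]
    rng = stream(sd.seed, "standardize_diet")
    B = B or sd.B
    h = np.empty(B)
    for b in range(B):
        idx = rng.choice(n, size=sd.k, replace=False)
        m = M[idx].mean(axis=0)
        m = m[m > 0]
        h[b] = -(m * np.log(m)).sum()
    return float(h.mean())


def species_accumulation(profiles: list[DietProfile]) -> pd.DataFrame:
    """Exact expected cumulative richness versus number of samples.

    For N samples and taxon i occurring in f_i of them,
    ``E[S_k] = sum_i [1 - C(N - f_i, k) / C(N, k)]`` — the expectation of the
    sample-based accumulation curve over all subsets of size k. Returns a
    frame with columns ``n_samples`` (1..N) and ``expected_richness``.
    """
    N = len(profiles)
    if N < 2:
        raise ValueError("need >= 2 samples for an accumulation curve")
    occ = _profile_matrix(profiles).to_numpy() > 0
    f = occ.sum(axis=0).astype(float)
    ks = np.arange(1, N + 1)
    exp_rich = [
        float((1.0 - comb(N - f, k) / comb(N, k)).sum()) for k in ks
    ]
    return pd.DataFrame({"n_samples": ks, "expected_richness": exp_rich})


def diet_quality_dp(
    sd: StandardizedDiet, traits: pd.Series, occurrence_weighted: bool = False
) -> DietQuality:
    """RRA-weighted digestible-protein content of a standardized diet.

    Taxa lacking a DP value are excluded and the weights renormalized;
    ``coverage`` reports the RRA mass that had trait data. With
    ``occurrence_weighted=True`` every covered taxon present in the diet is
    weighted equally instead (occurrence-based sensitivity check).
    """
    rra = sd.mean_rra[sd.mean_rra > 0]
    covered = rra.index.intersection(traits.dropna().index)
    if len(covered) == 0:
        raise ValueError(f"individual {sd.individual_id!r}: no taxon has DP data")
    w = rra.loc[covered]
    coverage = float(w.sum())
    dp = traits.loc[covered].astype(float)
    if occurrence_weighted:
        value = float(dp.mean())
    else:
        value = float((w * dp).sum() / w.sum())
    return DietQuality(sd.individual_id, value, coverage)


def single_sample_richness(
    profiles: list[DietProfile], B: int = 1000, seed: int = 0
) -> float:
    """Mean occurrence richness of one uniformly drawn sample (B trials)."""
    if not profiles:
        raise ValueError("need >= 1 sample")
    rich = np.array([int(p.occurrence.sum()) for p in profiles], dtype=float)
    rng = stream(seed, "single_sample_richness")
    idx = rng.integers(0, len(profiles), size=B)
    return float(rich[idx].mean())
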