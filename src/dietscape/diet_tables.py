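"""Post-bioinformatics processing of metabarcoding read tables.

Pipeline order is fixed: PCR-replicate averaging, then the within-sample 1%
relative-abundance filter, then rarefaction to a common depth, then
conversion to relative-read-abundance (RRA) profiles. The filter/rarefaction
order can be swapped via ``filter_before_rarefaction=False`` for sensitivity
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream

logger = logging.getLogger(__name__)

__all__ = [
    "ReadCountTable",
    "DietProfile",
    "average_pcr_replicates",
    "filter_rare_motus",
    "rarefy_sample",
    "rarefy_table",
    "to_profiles",
    "process_reads",
]


@dataclass
class ReadCountTable:
    """Sample-by-mOTU read counts with optional PCR-replicate substructure.

    ``counts`` is indexed by (sample_id, pcr_rep) while replicates are
    present, and by sample_id after averaging. ``samples`` maps sample_id to
    per-sample metadata (at minimum ``individual_id``).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be nonnegative")
        if "individual_id" not in self.samples.columns:
            raise ValueError("sample table must carry individual_id")

    @property
    def has_replicates(self) -> bool:
        return isinstance(self.counts.index, pd.MultiIndex)

    @property
    def motus(self) -> list:
        return list(self.counts.columns)

    @classmethod
    def from_long(cls, reads: pd.DataFrame, samples: pd.DataFrame) -> "ReadCountTable":
        """Build from long-format reads (sample_id, pcr_rep, motu_id, count)."""
        required = {"sample_id", "pcr_rep", "motu_id", "count"}
        missing = required - set(reads.columns)
        if missing:
            raise ValueError(f"reads table missing columns: {sorted(missing)}")
        wide = (
            reads.pivot_table(
                index=["sample_id", "pcr_rep"],
                columns="motu_id",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .sort_index()
        )
        wide.columns.name = None
        return cls(wide, samples.set_index("sample_id") if "sample_id" in samples.columns else samples)


@dataclass
class DietProfile:
    sample_id: object
    rra: pd.Series
    occurrence: pd.Series
    retained_depth: int


def average_pcr_replicates(table: ReadCountTable, round_half_up: bool = True) -> ReadCountTable:
    """Collapse PCR replicates to one row per physical sample.

    Each cell becomes the arithmetic mean of its replicate counts. Means are
    rounded half-up to integers (rarefaction needs integer counts); pass
    ``round_half_up=False`` to keep real values. Samples with zero retained
    replicates cannot occur here (they simply have no rows); samples whose
    replicates are all-zero are kept and dropped later by :func:`to_profiles`.
    """
    if not table.has_replicates:
        return table
    mean = table.counts.groupby(level="sample_id", sort=True).mean()
    if round_half_up:
        mean = np.floor(mean + 0.5).astype(np.int64)
    return ReadCountTable(mean, table.samples)


def filter_rare_motus(table: ReadCountTable, threshold: float = 0.01) -> ReadCountTable:
    """Zero out taxa below a within-sample read-fraction threshold.

    A taxon is removed from a sample when its share of that sample's reads is
    strictly less than ``threshold``; taxa at exactly the threshold are kept.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    if threshold == 0:
        return table
    X = table.counts.to_numpy(dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.divide(X, totals, out=np.zeros_like(X), where=totals > 0)
    filtered = table.counts.where(pd.DataFrame(frac >= threshold,
                                               index=table.counts.index,
                                               columns=table.counts.columns), 0)
    return ReadCountTable(filtered, table.samples)


def rarefy_sample(counts, depth: int = 7000, seed: int = 0) -> np.ndarray:
    """Subsample one sample's counts without replacement to exactly ``depth``.

    Multivariate hypergeometric draw. Raises if the sample holds fewer than
    ``depth`` reads; table-level handling (dropping shallow samples) lives in
    :func:`rarefy_table`.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers (round replicates first)")
        counts = np.round(counts).astype(np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample has {total} reads < depth {depth}")
    if total == depth:
        return counts.copy()
    rng = stream(seed, "rarefy")
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_table(table: ReadCountTable, depth: int = 7000, seed: int = 0) -> ReadCountTable:
    """Rarefy every sample to ``depth``; drop under-depth samples with a warning."""
    rows = {}
    for i, (sid, row) in enumerate(table.counts.iterrows()):
        total = int(row.sum())
        if total < depth:
            logger.warning("dropping sample %s: %d reads < depth %d", sid, total, depth)
            continue
        rows[sid] = rarefy_sample(row.to_numpy(), depth=depth, seed=seed + i)
    if not rows:
        raise ValueError("no samples reach the rarefaction depth")
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.counts.columns)
    out.index.name = table.counts.index.name or "sample_id"
    return ReadCountTable(out, table.samples.loc[list(rows)])


def to_profiles(table: ReadCountTable) -> list[DietProfile]:
    """Convert a (rarefied) table to per-sample RRA and occurrence profiles."""
    profiles = []
    for sid, row in table.counts.iterrows():
        total = row.sum()
        if total == 0:
            logger.warning("dropping all-zero sample %s", sid)
            continue
        rra = row / total
        profiles.append(
            DietProfile(sid, rra.astype(float), (rra > 0).astype(int), int(total))
        )
    return profiles


def process_reads(
    table: ReadCountTable,
    threshold: float = 0.01,
    depth: int = 7000,
    seed: int = 0,
    filter_before_rarefaction: bool = True,
) -> list[DietProfile]:
    """Full post-bioinformatics chain: average, filter, rarefy, profile."""
    t = average_pcr_replicates(table)
    if filter_before_rarefaction:
        t = filter_rare_motus(t, threshold)
        t = rarefy_table(t, depth=depth, seed=seed)
    else:
        t = rarefy_table(t, depth=depth, seed=seed)
        t = filter_rare_motus(t, threshold)
    return to_profiles(t)


def profiles_to_frame(profiles: list[DietProfile]) -> pd.DataFrame:
    """Stack profiles into a samples-by-mOTU RRA matrix."""
    return pd.DataFrame({p.sample_id: p.rra for p in profiles}).T.fillna(0.0)
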