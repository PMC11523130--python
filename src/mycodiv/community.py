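"""Count filtering, abundance transforms, taxonomic collapse, Venn
partitions of shared/unique features, and analytic rarefaction."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .tables import FeatureTable, SampleMetadata, TaxonomyMap, RANKS, UNIDENTIFIED

__all__ = [
    "filter_low_count",
    "relative_abundance",
    "collapse_taxonomy",
    "VennPartition",
    "venn_partition",
    "rarefaction_curve",
]


def filter_low_count(table: FeatureTable, min_count: int = 4,
                     per_sample: bool = True) -> FeatureTable:
    """Drop features never observed at ``min_count`` reads.

    With ``per_sample=True`` (default) a feature is kept iff *some*
    sample (library) holds at least ``min_count`` reads of it — the
    per-library minimum-count filter used by MicrobiomeAnalyst-style
    prevalence screens.  With ``per_sample=False`` the criterion is the
    feature's total count across samples.
    """
    if table.is_relative:
        raise ValueError("low-count filtering requires raw counts, "
                         "not relative abundances")
    if min_count <= 0:
        return FeatureTable(table.data.copy(), is_relative=False)
    if per_sample:
        keep = (table.data >= min_count).any(axis=1)
    else:
        keep = table.data.sum(axis=1) >= min_count
    return FeatureTable(table.data.loc[keep].copy(), is_relative=False)


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Convert counts to per-sample proportions (columns sum to 1)."""
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0].index.tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total count: {zero}")
    return FeatureTable(table.data.div(sums, axis=1), is_relative=True)


def collapse_taxonomy(table: FeatureTable, tax: TaxonomyMap,
                      rank: str) -> FeatureTable:
    """Sum feature rows by their taxon name at ``rank``.

    Features unmapped or unassigned at that rank pool into the
    ``unidentified`` row.  Per-sample column sums are conserved exactly.
    """
    if rank not in RANKS[1:6]:
        raise ValueError(f"rank must be one of {RANKS[1:6]}, got {rank!r}")
    names = [tax.at_rank(fid, rank) for fid in table.feature_ids]
    collapsed = table.data.groupby(pd.Index(names, name=None), sort=True).sum()
    # keep "unidentified" last for readability
    if UNIDENTIFIED in collapsed.index:
        order = [n for n in collapsed.index if n != UNIDENTIFIED] + [UNIDENTIFIED]
        collapsed = collapsed.loc[order]
    return FeatureTable(collapsed, is_relative=table.is_relative)


@dataclass
class VennPartition:
    """Disjoint regions of feature presence across k sample supersets.

    ``regions`` maps a frozenset of superset labels (the exact set of
    supersets a feature is present in) to the set of feature IDs in that
    region; all 2^k - 1 non-empty label combinations appear as keys.
    """

    group_labels: tuple
    regions: dict

    def sizes(self) -> dict:
        return {labels: len(fids) for labels, fids in self.regions.items()}

    def region(self, *labels) -> set:
        return self.regions[frozenset(labels)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for labels in sorted(self.regions, key=lambda s: (len(s), sorted(s))):
            fids = self.regions[labels]
            rows.append({
                "region": "&".join(sorted(labels)),
                "size": len(fids),
                "features": ",".join(sorted(map(str, fids))),
            })
        return pd.DataFrame(rows, columns=["region", "size", "features"])


def venn_partition(table: FeatureTable, meta: SampleMetadata,
                   grouping: dict | None = None) -> VennPartition:
    """Partition features by which sample supersets they occur in.

    ``grouping`` maps each metadata group label to a superset label
    (e.g. treatments to farmer / partial-CA / full-CA management
    classes); identity if omitted.  A feature is present in a superset
    iff it has count > 0 in at least one of its samples.  Regions are
    pairwise disjoint and cover every feature present anywhere.
    """
    sample_groups = meta.groups_for(table.sample_ids)
    if grouping is None:
        grouping = {g: g for g in np.unique(sample_groups)}
    missing = sorted(set(sample_groups) - set(grouping))
    if missing:
        raise ValueError(f"group(s) without a superset mapping: {missing}")
    supersets = sorted(set(grouping.values()))
    present = {}
    for label in supersets:
        cols = [s for s, g in zip(table.sample_ids, sample_groups)
                if grouping[g] == label]
        present[label] = (table.data[cols] > 0).any(axis=1)

    regions = {}
    for k in range(1, len(supersets) + 1):
        for combo in combinations(supersets, k):
            regions[frozenset(combo)] = set()
    membership = pd.DataFrame(present)
    for fid, row in membership.iterrows():
        labels = frozenset(membership.columns[row.to_numpy(dtype=bool)])
        if labels:
            regions[labels].add(fid)
    return VennPartition(group_labels=tuple(supersets), regions=regions)


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected species richness when subsampling without replacement.

    For a sample with species counts ``N_i`` summing to ``N``, the
    expected number of species seen in a random subsample of size n is

        E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]

    evaluated in log space (gammaln) for numerical stability.  The curve
    is non-decreasing in depth and bounded by the observed richness.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    counts = counts[counts > 0]
    N = counts.sum()
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if (depths < 0).any() or (depths > N).any():
        raise ValueError(f"depths must lie in [0, {int(N)}]")
    if np.any(np.diff(depths) < 0):
        raise ValueError("depths must be non-decreasing")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths), dtype=float)
    for j, n in enumerate(depths):
        # log C(N - N_i, n) - log C(N, n); species with N - N_i < n can
        # never be absent from the subsample
        absent = np.zeros_like(counts)
        ok = (N - counts) >= n
        absent[ok] = np.exp(log_choose(N - counts[ok], n) - log_choose(N, n))
        out[j] = float(np.sum(1.0 - absent))
    return out
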