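"""Core tabular containers for community and soil data.

All downstream statistics consume one of three validated containers:

* :class:`FeatureTable` — OTU/ASV counts, features as rows, samples as
  columns (the QIIME2 TSV export convention).
* :class:`SampleMetadata` — sample → treatment group and replicate index.
* :class:`SoilTable` — observations (treatments or treatment×replicate)
  × named quantitative soil indicators.

Validation happens at construction so every operation downstream can
assume the invariants (unique IDs, non-negative counts, finite values)
without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "SoilTable",
    "TaxonomyMap",
    "RANKS",
    "UNIDENTIFIED",
    "INDICATOR_UNITS",
]

#: Taxonomic ranks in lineage order, as used by QIIME2-style strings.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Label used for ranks that were not assigned by the classifier.
UNIDENTIFIED = "unidentified"

#: Units of the soil indicators as measured in the field study.
INDICATOR_UNITS = {
    "pH": "unitless",
    "EC": "dS/m",
    "SOC": "g/kg",
    "N": "kg/ha",
    "P": "kg/ha",
    "K": "kg/ha",
    "Fe": "mg/kg",
    "Mn": "mg/kg",
    "Zn": "mg/kg",
    "Cu": "mg/kg",
    "earthworm_count": "count/m3",
}


class TableFormatError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids, kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate {kind} ID(s): {dupes}")


@dataclass
class FeatureTable:
    """Feature (OTU/ASV) abundance matrix, features × samples.

    Parameters
    ----------
    data:
        DataFrame with feature IDs as index and sample IDs as columns.
        Entries are raw counts unless ``is_relative`` is set, in which
        case each sample column must sum to 1.
    is_relative:
        Whether ``data`` holds relative abundances.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self.data.columns[
                [not np.issubdtype(d, np.number) for d in self.data.dtypes]
            ].tolist()
            raise TableFormatError(f"non-numeric column(s): {bad}")
        if not np.all(np.isfinite(values)):
            raise TableFormatError("non-finite entries in feature table")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableFormatError(
                f"negative count at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.is_relative:
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise TableFormatError(
                    "relative-abundance columns must each sum to 1"
                )

    @property
    def feature_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def __eq__(self, other) -> bool:  # value semantics, used by round-trip tests
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.is_relative == other.is_relative
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.data.to_numpy(), other.data.to_numpy())
        )


@dataclass
class SampleMetadata:
    """Sample → treatment group / replicate mapping."""

    data: pd.DataFrame  # index: sample-id; columns: group, replicate

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("group", "replicate"):
            if col not in self.data.columns:
                raise TableFormatError(f"metadata missing column {col!r}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    def group_of(self, sample_id) -> str:
        try:
            return self.data.loc[sample_id, "group"]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in metadata") from None

    def groups_for(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"sample(s) missing from metadata: {missing}")
        return self.data.loc[list(sample_ids), "group"].to_numpy()

    def check_grouped(self, sample_ids, min_groups: int = 2,
                      min_per_group: int = 2) -> None:
        """Validate group structure required by ANOSIM / Kruskal-Wallis."""
        groups = pd.Series(self.groups_for(sample_ids))
        sizes = groups.value_counts()
        if len(sizes) < min_groups:
            raise ValueError(f"need >= {min_groups} groups, found {len(sizes)}")
        if (sizes < min_per_group).any():
            small = sizes[sizes < min_per_group].index.tolist()
            raise ValueError(
                f"group(s) with < {min_per_group} samples: {small}"
            )


@dataclass
class SoilTable:
    """Observations × quantitative soil indicators (the SQI input).

    Index is the observation ID (a treatment, or treatment×replicate);
    columns are indicator names.  Units default to the field-study
    conventions in :data:`INDICATOR_UNITS` for known indicators.
    """

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "observation")
        _check_unique(self.data.columns, "indicator")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableFormatError("soil table has non-numeric entries")
        if not np.all(np.isfinite(values)):
            rows, cols = np.argwhere(~np.isfinite(values)).T
            cells = [
                (self.data.index[r], self.data.columns[c])
                for r, c in zip(rows, cols)
            ]
            raise TableFormatError(f"missing/non-finite soil value(s) at {cells}")
        units = dict(INDICATOR_UNITS)
        units.update(self.units)
        self.units = {c: units.get(c, "unknown") for c in self.data.columns}

    @property
    def observation_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def indicators(self) -> list:
        return self.data.columns.tolist()

    @property
    def n_observations(self) -> int:
        return self.data.shape[0]


@dataclass
class TaxonomyMap:
    """feature_id → ranked lineage (kingdom … species).

    Lineages shorter than seven ranks are padded with ``unidentified``.
    """

    lineages: dict  # feature_id -> tuple of 7 rank names

    def __post_init__(self) -> None:
        fixed = {}
        for fid, lineage in self.lineages.items():
            lineage = tuple(lineage)
            if len(lineage) > len(RANKS):
                raise TableFormatError(
                    f"lineage for {fid!r} deeper than {len(RANKS)} ranks"
                )
            lineage = lineage + (UNIDENTIFIED,) * (len(RANKS) - len(lineage))
            fixed[fid] = tuple(
                name if name else UNIDENTIFIED for name in lineage
            )
        self.lineages = fixed

    def at_rank(self, feature_id, rank: str) -> str:
        """Taxon name of ``feature_id`` at ``rank`` (``unidentified`` if unmapped)."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
        lineage = self.lineages.get(feature_id)
        if lineage is None:
            return UNIDENTIFIED
        return lineage[RANKS.index(rank)]

    def __len__(self) -> int:
        return len(self.lineages)
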