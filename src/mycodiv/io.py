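"""Readers and writers for the plain-text table formats.

Feature tables are tab-separated with features as rows and samples as
columns (QIIME2 TSV export convention; a leading ``#OTU ID`` header token
is tolerated).  Soil tables are CSV with one row per observation.
Metadata is TSV with columns ``sample-id``, ``group``, ``replicate``.
Taxonomy is TSV mapping feature IDs to ``;``-separated lineage strings
with optional QIIME-style rank prefixes (``k__``, ``p__``, ...).
"""

from __future__ import annotations

import importlib.resources
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    FeatureTable,
    SampleMetadata,
    SoilTable,
    TableFormatError,
    TaxonomyMap,
)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_soil_table",
    "write_soil_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "load_reference_soil_table",
]

_RANK_PREFIX = re.compile(r"^[a-z]__")


def read_feature_table(path) -> FeatureTable:
    """Read a features × samples count table from TSV.

    First column holds feature IDs, header row holds sample IDs.
    Raises :class:`TableFormatError` on duplicate IDs or negative /
    non-numeric cells, naming the offending row and column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise TableFormatError(f"{path}: duplicate sample ID(s): {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.empty and df.shape[1] == 0:
        raise TableFormatError(f"{path}: empty feature table")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = [str(c) for c in df.columns]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise TableFormatError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r}"
            )
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise TableFormatError(
                f"{path}: missing cell at feature {row!r}, sample {col!r}"
            )
        df[col] = coerced
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.data.copy()
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_soil_table(path, units: dict | None = None) -> SoilTable:
    """Read an observations × indicators CSV into a :class:`SoilTable`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty soil table") from None
    if df.shape[1] == 0:
        raise TableFormatError(f"{path}: soil table has no indicator columns")
    df.index = df.index.astype(str)
    df.index.name = None
    return SoilTable(df.astype(float), units=units or {})


def write_soil_table(table: SoilTable, path) -> None:
    out = table.data.copy()
    out.index.name = "observation"
    out.to_csv(path, float_format="%.10g")


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV (columns sample-id, group, replicate)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for col in df.columns:
        key = col.strip().lower().replace("_", "-")
        if key in ("sample-id", "sampleid", "#sample-id"):
            rename[col] = "sample_id"
        elif key in ("group", "treatment"):
            rename[col] = "group"
        elif key == "replicate":
            rename[col] = "replicate"
    df = df.rename(columns=rename)
    if "sample_id" not in df.columns:
        raise TableFormatError(f"{path}: no sample-id column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    df.index.name = None
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.data.copy()
    out.index.name = "sample-id"
    out.to_csv(path, sep="\t")


def parse_lineage(text: str) -> tuple:
    """Split a ``;``-separated lineage string, stripping rank prefixes.

    ``"k__Fungi;p__Ascomycota"`` → ``("Fungi", "Ascomycota")``.
    """
    parts = [p.strip() for p in str(text).split(";")]
    return tuple(
        _RANK_PREFIX.sub("", p) for p in parts if _RANK_PREFIX.sub("", p)
    )


def read_taxonomy(path) -> TaxonomyMap:
    """Read a feature-id → lineage TSV into a :class:`TaxonomyMap`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["feature_id", "lineage"], dtype=str)
    if df["feature_id"].duplicated().any():
        dupes = df["feature_id"][df["feature_id"].duplicated()].tolist()
        raise TableFormatError(f"{path}: duplicate taxonomy row(s) for {dupes}")
    return TaxonomyMap(
        {fid: parse_lineage(lin) for fid, lin in
         zip(df["feature_id"], df["lineage"].fillna(""))}
    )


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    prefixes = "kpcofgs"
    with open(path, "w") as fh:
        for fid, lineage in tax.lineages.items():
            joined = ";".join(
                f"{prefixes[i]}__{name}" for i, name in enumerate(lineage)
            )
            fh.write(f"{fid}\t{joined}\n")


def load_reference_soil_table() -> SoilTable:
    """Packaged per-treatment soil chemistry and earthworm counts.

    Seven treatment means for pH, EC, SOC, macro- and micronutrients and
    earthworm counts from the long-term conservation-agriculture trial;
    the standard worked input for the soil-quality-index pipeline.
    """
    ref = importlib.resources.files("mycodiv.data") / "table1_soil.csv"
    with importlib.resources.as_file(ref) as path:
        return read_soil_table(path)
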