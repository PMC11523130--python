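"""End-to-end pipeline: filter → alpha → beta → community → SQI →
group statistics, driven by a YAML config, writing one TSV per result
family plus a JSON run manifest.  Deterministic given the seed."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import alpha_table
from .beta import anosim, bray_curtis, pcoa
from .community import (
    collapse_taxonomy,
    filter_low_count,
    relative_abundance,
    venn_partition,
)
from .group_stats import kruskal_wallis
from .io import read_feature_table, read_metadata, read_soil_table, read_taxonomy
from .soil_quality import LESS_IS_BETTER, MORE_IS_BETTER, sqi_pipeline

logger = logging.getLogger("mycodiv")

__all__ = ["PipelineConfig", "run_pipeline"]

#: Floats in output TSVs are written with 6 significant digits.
FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    feature_table: str
    metadata: str
    taxonomy: str | None = None
    soil_table: str | None = None
    output_dir: str = "mycodiv_out"
    min_count: int = 4
    min_count_per_sample: bool = True
    alpha_indices: tuple = ("observed", "chao1", "ace", "shannon",
                            "simpson", "fisher")
    permutations: int = 999
    seed: int = 0
    collapse_rank: str = "phylum"
    venn_grouping: dict | None = None
    soil_level: str = "treatment"   # treatment means or replicate rows
    directions: dict = field(default_factory=dict)
    sqi_a: float = 1.0
    sqi_slope: float = 2.5
    eig_min: float = 0.9
    var_min: float = 5.0
    loading_floor: float = 0.40
    loading_window: float = 0.10
    r_max: float = 0.60

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        for name in ("permutations", "sqi_a", "sqi_slope", "eig_min",
                     "var_min", "loading_floor", "loading_window",
                     "r_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        bad = [v for v in self.directions.values()
               if v not in (MORE_IS_BETTER, LESS_IS_BETTER)]
        if bad:
            raise ValueError(f"invalid direction(s): {bad}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "alpha_indices" in raw:
            raw["alpha_indices"] = tuple(raw["alpha_indices"])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write results under ``config.output_dir``.

    Returns a manifest dict (also written as ``manifest.json``) listing
    parameters, the seed, package version, and the files produced.
    Repeated runs with the same inputs and seed are byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict = {}

    table = read_feature_table(config.feature_table)
    meta = read_metadata(config.metadata)

    if config.min_count > 0:
        filtered = filter_low_count(table, config.min_count,
                                    per_sample=config.min_count_per_sample)
        logger.info("low-count filter (min_count=%d): %d -> %d features",
                    config.min_count, table.n_features, filtered.n_features)
    else:
        filtered = table
        logger.info("min_count=0: filter stage is a no-op")

    # alpha diversity + per-index Kruskal-Wallis across treatments
    alpha = alpha_table(filtered, indices=config.alpha_indices)
    _write(alpha, out / "alpha_diversity.tsv", files, index_label="sample-id")
    groups = meta.groups_for(alpha.index)
    kw_rows = []
    for idx in alpha.columns:
        vals = alpha[idx].to_numpy()
        if np.isnan(vals).any():
            continue
        res = kruskal_wallis(vals, groups)
        kw_rows.append({"index": idx, "H": res.statistic,
                        "df": res.df[0], "p_value": res.p_value})
    _write(pd.DataFrame(kw_rows), out / "alpha_kruskal_wallis.tsv", files,
           index=False)

    # beta diversity: distances, ordination, ANOSIM
    dm = bray_curtis(filtered)
    _write(dm.to_frame(), out / "bray_curtis.tsv", files,
           index_label="sample-id")
    ordination = pcoa(dm)
    _write(ordination.to_frame(), out / "pcoa_coordinates.tsv", files,
           index_label="sample-id")
    (out / "pcoa_eigenvalues.json").write_text(json.dumps({
        "eigenvalues": [float(f"{v:.6g}") for v in ordination.eigenvalues],
        "proportion_explained":
            [float(f"{v:.6g}") for v in ordination.proportion_explained],
    }, indent=2))
    files["pcoa_eigenvalues"] = "pcoa_eigenvalues.json"
    ano = anosim(dm, meta, permutations=config.permutations,
                 seed=config.seed)
    (out / "anosim.json").write_text(json.dumps({
        "R": float(f"{ano.r:.6g}"), "p_value": float(f"{ano.p_value:.6g}"),
        "permutations": ano.permutations, "seed": ano.seed,
    }, indent=2))
    files["anosim"] = "anosim.json"

    # community composition
    rel = relative_abundance(filtered)
    if config.taxonomy:
        tax = read_taxonomy(config.taxonomy)
        collapsed = collapse_taxonomy(rel, tax, config.collapse_rank)
        _write(collapsed.data, out / f"{config.collapse_rank}_abundance.tsv",
               files, index_label="taxon")
    venn = venn_partition(filtered, meta, grouping=config.venn_grouping)
    _write(venn.to_frame(), out / "venn_regions.tsv", files, index=False)

    # soil quality index
    if config.soil_table:
        soil = read_soil_table(config.soil_table)
        result = sqi_pipeline(
            soil, directions=config.directions, eig_min=config.eig_min,
            var_min=config.var_min, loading_floor=config.loading_floor,
            loading_window=config.loading_window, r_max=config.r_max,
            a=config.sqi_a, slope=config.sqi_slope,
        )
        sqi_out = result.scores.copy()
        sqi_out["SQI"] = result.sqi
        _write(sqi_out, out / "sqi.tsv", files, index_label="observation")
        (out / "sqi_audit.json").write_text(json.dumps({
            "soil_level": config.soil_level,
            "retained_pcs": [
                {"pc": pc, "eigenvalue": float(f"{lam:.6g}"),
                 "variance_pct": float(f"{var:.6g}")}
                for pc, lam, var in result.selection.retained_pcs
            ],
            "weights": {i: float(f"{w:.6g}")
                        for i, w in result.selection.weights.items()},
            "log": result.selection.log,
        }, indent=2))
        files["sqi_audit"] = "sqi_audit.json"

    manifest = {
        "package": "mycodiv",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "outputs": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write(df: pd.DataFrame, path: Path, files: dict, index: bool = True,
           index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index,
              index_label=index_label)
    files[path.stem] = path.name
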