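"""PCA-based soil quality index (SQI).

The pipeline condenses a table of soil indicators (pH, salinity, organic
carbon, macro/micronutrients, earthworm counts, ...) into a single
per-observation quality score in three steps:

1. **Minimum data set (MDS) selection.**  A standardized PCA on the
   indicator correlation matrix identifies the components that carry the
   signal (eigenvalue and variance-share thresholds).  Within each
   retained component, highly loaded indicators are candidates; among
   correlated candidates only the most heavily loaded survives, so the
   MDS is a small, weakly redundant indicator subset.  Each MDS
   indicator inherits a weight from its source component's share of the
   retained variance.

2. **Non-linear scoring.**  Each indicator value x maps onto (0, 1)
   through the sigmoid

       S = a / (1 + (x / x0)^b)

   with asymptote a = 1, baseline x0 the indicator's mean across
   observations, and slope b = -2.5 for "more is better" indicators
   (score rises with x) or +2.5 for "less is better" ones such as
   salinity (score falls with x).  S(x0) = a/2 in either direction, and
   S depends on x only through x / x0, so rescaling an indicator's units
   never changes its scores.

3. **Aggregation.**  SQI = sum_i W_i S_i over the MDS indicators, a
   weighted score in (0, 1] when the weights sum to 1.

Every inclusion/exclusion decision of step 1 is recorded in an audit
log so the selection path is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .tables import SoilTable

__all__ = [
    "PcaResult",
    "MdsSelection",
    "ScoringSpec",
    "SqiResult",
    "standardized_pca",
    "select_mds",
    "score_indicator",
    "compute_sqi",
    "sqi_pipeline",
    "MORE_IS_BETTER",
    "LESS_IS_BETTER",
    "DEFAULT_DIRECTIONS",
]

MORE_IS_BETTER = "more_is_better"
LESS_IS_BETTER = "less_is_better"

#: Scoring direction for the standard field-study indicators: higher is
#: better for fertility/biology indicators; lower is better for EC
#: (salinity stress).
DEFAULT_DIRECTIONS = {
    "pH": MORE_IS_BETTER,
    "EC": LESS_IS_BETTER,
    "SOC": MORE_IS_BETTER,
    "N": MORE_IS_BETTER,
    "P": MORE_IS_BETTER,
    "K": MORE_IS_BETTER,
    "Fe": MORE_IS_BETTER,
    "Mn": MORE_IS_BETTER,
    "Zn": MORE_IS_BETTER,
    "Cu": MORE_IS_BETTER,
    "earthworm_count": MORE_IS_BETTER,
}


@dataclass
class PcaResult:
    """Eigendecomposition of the indicator correlation matrix.

    ``loadings`` columns are unit-norm eigenvectors (indicator × PC);
    ``variance_pct`` is each PC's percentage of total variance
    (eigenvalue / number of indicators × 100 for a correlation-matrix
    PCA).  Means/SDs are the standardization constants (ddof = 1).
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame          # index: indicators, columns: PC1..PCk
    variance_pct: np.ndarray
    means: pd.Series
    sds: pd.Series


def standardized_pca(soil: SoilTable) -> PcaResult:
    """PCA of z-scored indicators via the correlation matrix.

    Each indicator is centred and scaled to unit variance (denominator
    n - 1); the correlation matrix is eigendecomposed and components
    are returned in descending eigenvalue order.  A constant indicator
    (zero variance) is an error, named in the message.
    """
    if soil.n_observations < 3:
        raise ValueError("PCA needs at least 3 observations")
    x = soil.data.to_numpy(dtype=float)
    means = soil.data.mean(axis=0)
    sds = soil.data.std(axis=0, ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant indicator(s): {constant}")
    z = (x - means.to_numpy()) / sds.to_numpy()
    corr = (z.T @ z) / (soil.n_observations - 1)
    evals, evecs = np.linalg.eigh((corr + corr.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    pcs = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=soil.indicators, columns=pcs)
    variance_pct = 100.0 * evals / evals.sum()
    return PcaResult(eigenvalues=evals, loadings=loadings,
                     variance_pct=variance_pct, means=means, sds=sds)


@dataclass
class MdsSelection:
    """Audit record of the minimum-data-set screen.

    ``weights`` maps each final MDS indicator to W_i (summing to 1);
    ``source_pc`` maps it to the retained component it came from;
    ``retained_pcs`` lists (PC name, eigenvalue, variance %);
    ``candidates`` maps PC name → candidate indicators with loadings;
    ``log`` is the ordered list of human-readable decisions.
    """

    retained_pcs: list
    candidates: dict
    weights: dict
    source_pc: dict
    log: list = field(default_factory=list)

    @property
    def indicators(self) -> list:
        return list(self.weights)


def select_mds(pca: PcaResult, soil: SoilTable,
               eig_min: float = 0.9, var_min: float = 5.0,
               loading_floor: float = 0.40, loading_window: float = 0.10,
               r_max: float = 0.60) -> MdsSelection:
    """Screen indicators down to a minimum data set with PCA weights.

    Rules, applied in order and logged:

    1. Retain PCs with eigenvalue >= ``eig_min`` **and** variance share
       >= ``var_min`` percent.
    2. Per retained PC, candidate indicators have absolute loading
       >= ``loading_floor`` or within ``loading_window`` × the PC's
       maximum absolute loading of that maximum.
    3. If a PC has several candidates, keep the highest-|loading| one,
       then admit the rest in descending |loading| order only while
       their Pearson correlation (on raw values) with every kept
       candidate of that PC stays below ``r_max`` in magnitude.
    4. W_i = (variance % of the source PC) / (sum of variance % over all
       retained PCs); a PC contributing m indicators splits its weight
       m ways; weights are finally renormalized to sum to 1.

    Loading signs are ignored throughout (eigenvector sign is
    arbitrary).
    """
    log: list = []
    retained = []
    for k, pc in enumerate(pca.loadings.columns):
        lam, var = pca.eigenvalues[k], pca.variance_pct[k]
        if lam >= eig_min and var >= var_min:
            retained.append((pc, float(lam), float(var)))
            log.append(f"retain {pc}: eigenvalue {lam:.4f} >= {eig_min}, "
                       f"variance {var:.2f}% >= {var_min}%")
        else:
            log.append(f"drop {pc}: eigenvalue {lam:.4f}, variance {var:.2f}%")
    if not retained:
        raise ValueError(
            f"no principal component passes eigenvalue >= {eig_min} and "
            f"variance >= {var_min}%; lower the thresholds"
        )

    candidates: dict = {}
    kept_by_pc: dict = {}
    for pc, lam, var in retained:
        load = pca.loadings[pc].abs()
        top = load.max()
        cand = load[(load >= loading_floor) |
                    (load >= top * (1.0 - loading_window))]
        cand = cand.sort_values(ascending=False)
        candidates[pc] = dict(cand)
        log.append(f"{pc} candidates (|loading| >= {loading_floor} or within "
                   f"{loading_window:.0%} of max {top:.4f}): "
                   f"{', '.join(f'{i}={v:.4f}' for i, v in cand.items())}")
        kept: list = []
        for ind in cand.index:
            if not kept:
                kept.append(ind)
                log.append(f"{pc}: keep {ind} (highest |loading|)")
                continue
            rs = {
                other: float(pearsonr(soil.data[ind], soil.data[other])[0])
                for other in kept
            }
            clash = {o: r for o, r in rs.items() if abs(r) >= r_max}
            if clash:
                worst = max(clash.items(), key=lambda kv: abs(kv[1]))
                log.append(f"{pc}: exclude {ind} (|r| = {abs(worst[1]):.4f} "
                           f"with {worst[0]} >= {r_max})")
            else:
                kept.append(ind)
                log.append(f"{pc}: keep {ind} (max |r| with kept = "
                           f"{max((abs(r) for r in rs.values()), default=0.0):.4f}"
                           f" < {r_max})")
        kept_by_pc[pc] = kept

    total_var = sum(var for _, _, var in retained)
    weights: dict = {}
    source_pc: dict = {}
    for pc, lam, var in retained:
        kept = kept_by_pc[pc]
        for ind in kept:
            if ind in weights:  # indicator already claimed by a stronger PC
                log.append(f"{pc}: {ind} already in MDS via {source_pc[ind]}")
                continue
            weights[ind] = (var / total_var) / len(kept)
            source_pc[ind] = pc
    norm = sum(weights.values())
    weights = {ind: w / norm for ind, w in weights.items()}
    log.append("final MDS: " +
               ", ".join(f"{i} (W={w:.4f}, {source_pc[i]})"
                         for i, w in weights.items()))
    return MdsSelection(retained_pcs=retained, candidates=candidates,
                        weights=weights, source_pc=source_pc, log=log)


@dataclass
class ScoringSpec:
    """Per-indicator sigmoid scoring parameters.

    ``directions`` maps indicator → more_is_better / less_is_better;
    ``baselines`` maps indicator → x0 (> 0); ``a`` is the score
    asymptote and ``slope`` the magnitude of the exponent b.
    """

    directions: dict
    baselines: dict
    a: float = 1.0
    slope: float = 2.5

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("asymptote a must be positive")
        bad = [d for d in self.directions.values()
               if d not in (MORE_IS_BETTER, LESS_IS_BETTER)]
        if bad:
            raise ValueError(f"unknown direction(s): {bad}")
        nonpos = [i for i, x0 in self.baselines.items() if x0 <= 0]
        if nonpos:
            raise ValueError(f"baseline x0 must be > 0 for {nonpos}")

    def b_for(self, indicator: str) -> float:
        direction = self.directions.get(indicator)
        if direction is None:
            raise KeyError(f"no scoring direction for {indicator!r}")
        return -self.slope if direction == MORE_IS_BETTER else self.slope


def score_indicator(x: float, indicator: str, spec: ScoringSpec) -> float:
    """Sigmoid score S = a / (1 + (x / x0)^b) in (0, a).

    b = -slope for more-is-better (S increasing in x), +slope for
    less-is-better (S decreasing).  S(x0) = a/2 exactly either way.
    x must be positive (the power of a non-positive ratio is undefined).
    """
    if x <= 0:
        raise ValueError(f"indicator {indicator!r}: x must be > 0, got {x}")
    x0 = spec.baselines.get(indicator)
    if x0 is None:
        raise KeyError(f"no baseline x0 for {indicator!r}")
    b = spec.b_for(indicator)
    return spec.a / (1.0 + (x / x0) ** b)


@dataclass
class SqiResult:
    """Per-observation indicator scores and aggregate SQI."""

    scores: pd.DataFrame      # observations × MDS indicators
    sqi: pd.Series            # per observation
    selection: MdsSelection
    spec: ScoringSpec

    def ranking(self) -> pd.Series:
        return self.sqi.sort_values(ascending=False)


def compute_sqi(soil: SoilTable, selection: MdsSelection,
                spec: ScoringSpec) -> SqiResult:
    """Weighted aggregation SQI = sum_i W_i S_i over the MDS indicators."""
    missing = [i for i in selection.indicators if i not in soil.indicators]
    if missing:
        raise KeyError(f"MDS indicator(s) absent from soil table: {missing}")
    scores = pd.DataFrame(index=soil.data.index,
                          columns=selection.indicators, dtype=float)
    for ind in selection.indicators:
        scores[ind] = [score_indicator(x, ind, spec)
                       for x in soil.data[ind]]
    w = pd.Series(selection.weights)
    sqi = scores.mul(w, axis=1).sum(axis=1)
    sqi.name = "SQI"
    return SqiResult(scores=scores, sqi=sqi, selection=selection, spec=spec)


def sqi_pipeline(soil: SoilTable, directions: dict | None = None,
                 eig_min: float = 0.9, var_min: float = 5.0,
                 loading_floor: float = 0.40, loading_window: float = 0.10,
                 r_max: float = 0.60, a: float = 1.0,
                 slope: float = 2.5) -> SqiResult:
    """Full pipeline: standardized PCA → MDS screen → sigmoid scoring
    (x0 = per-indicator mean across observations) → weighted SQI.

    ``directions`` defaults to :data:`DEFAULT_DIRECTIONS` for known
    indicator names and more-is-better otherwise.
    """
    if directions is None:
        directions = {}
    dirs = {}
    for ind in soil.indicators:
        dirs[ind] = directions.get(
            ind, DEFAULT_DIRECTIONS.get(ind, MORE_IS_BETTER))
    pca = standardized_pca(soil)
    selection = select_mds(pca, soil, eig_min=eig_min, var_min=var_min,
                           loading_floor=loading_floor,
                           loading_window=loading_window, r_max=r_max)
    baselines = {ind: float(soil.data[ind].mean())
                 for ind in selection.indicators}
    spec = ScoringSpec(directions=dirs, baselines=baselines, a=a, slope=slope)
    return compute_sqi(soil, selection, spec)
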