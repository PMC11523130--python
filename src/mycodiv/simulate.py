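"""Synthetic data with the statistical structure of a replicated
tillage field trial.

Three generators cover the pipeline's inputs:

* :func:`gen_community` — Dirichlet-multinomial feature tables.  Each
  treatment group has a base fungal composition; every replicate draws
  its own composition from a Dirichlet centred on the group's base
  (concentration controls replicate-to-replicate variability) and then
  sequencing counts from a multinomial at the group's depth.  This is
  the standard overdispersed count model for amplicon data.

* :func:`gen_soil` — soil indicator tables: Gaussian replicate noise
  around per-treatment means (defaulting to the reference trial's
  per-treatment soil chemistry), truncated at zero for positive-support
  indicators; earthworm counts are negative-binomial.

* :func:`gen_known_sqi_case` — a planted-factor soil table whose
  minimum-data-set selection and SQI ordering are known by
  construction, for end-to-end recovery testing.

All generators are pure functions of (parameters, seed).  The default
design mirrors the reference trial: 7 treatments × 3 replicates,
~1 000 features at depth 30 000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import load_reference_soil_table
from .tables import FeatureTable, SampleMetadata, SoilTable

__all__ = [
    "SimulationTruth",
    "default_truth",
    "gen_community",
    "gen_soil",
    "gen_known_sqi_case",
]

#: Replicate coefficient of variation for soil chemistry (field plots of
#: the same treatment typically agree to within a few percent).
DEFAULT_SOIL_CV = 0.05

#: Negative-binomial dispersion for earthworm counts (variance =
#: mu + mu^2 / dispersion); moderate patchiness.
DEFAULT_EARTHWORM_DISPERSION = 30.0


@dataclass
class SimulationTruth:
    """Ground truth for a simulated trial.

    ``base_compositions``: group → probability vector over features
    (each sums to 1).  ``concentration``: Dirichlet concentration around
    the base (larger = tighter replicates).  ``depths``: group →
    sequencing depth.  ``soil_means``/``soil_sds``: per-treatment
    indicator means and replicate SDs.  ``earthworm_dispersion``:
    negative-binomial size parameter for the count indicator.
    """

    base_compositions: dict
    concentration: float
    depths: dict
    soil_means: pd.DataFrame
    soil_sds: pd.DataFrame
    earthworm_dispersion: float = DEFAULT_EARTHWORM_DISPERSION

    def __post_init__(self) -> None:
        for g, p in self.base_compositions.items():
            p = np.asarray(p, dtype=float)
            if not np.isclose(p.sum(), 1.0):
                raise ValueError(f"composition for {g!r} does not sum to 1")
            if (p < 0).any():
                raise ValueError(f"negative composition entries for {g!r}")
            self.base_compositions[g] = p
        if any(d <= 0 for d in self.depths.values()):
            raise ValueError("depths must be positive")
        if (self.soil_sds.to_numpy() < 0).any():
            raise ValueError("soil SDs must be non-negative")


def default_truth(n_features: int = 1000, n_groups: int = 7,
                  depth: int = 30000, concentration: float = 200.0,
                  effect: float = 1.0, seed: int = 0) -> SimulationTruth:
    """Reference-scale truth: 7 treatment compositions sharing a common
    log-normal rank-abundance backbone with group-specific log-normal
    tilts of strength ``effect`` (0 = identical groups)."""
    rng = np.random.default_rng(seed)
    backbone = rng.lognormal(mean=0.0, sigma=1.5, size=n_features)
    groups = [f"T{i + 1}" for i in range(n_groups)]
    comps = {}
    for g in groups:
        tilt = rng.lognormal(mean=0.0, sigma=effect, size=n_features)
        p = backbone * tilt
        comps[g] = p / p.sum()
    soil = load_reference_soil_table()
    means = soil.data.iloc[:n_groups].copy()
    means.index = groups[: len(means)]
    sds = means.abs() * DEFAULT_SOIL_CV
    return SimulationTruth(
        base_compositions=comps,
        concentration=concentration,
        depths={g: depth for g in groups},
        soil_means=means,
        soil_sds=sds,
    )


def gen_community(truth: SimulationTruth, reps: int = 3,
                  seed: int = 0) -> tuple[FeatureTable, SampleMetadata]:
    """Draw a Dirichlet-multinomial feature table for the trial design.

    Per sample: composition ~ Dirichlet(concentration × base), counts ~
    Multinomial(depth, composition).  Column sums equal the configured
    depths exactly.
    """
    rng = np.random.default_rng(seed)
    groups = list(truth.base_compositions)
    n_features = len(next(iter(truth.base_compositions.values())))
    cols, meta_rows = {}, []
    for g in groups:
        base = truth.base_compositions[g]
        alpha = np.maximum(truth.concentration * base, 1e-9)
        for r in range(1, reps + 1):
            sid = f"{g}R{r}"
            p = rng.dirichlet(alpha)
            cols[sid] = rng.multinomial(int(truth.depths[g]), p)
            meta_rows.append({"sample_id": sid, "group": g, "replicate": r})
    features = [f"OTU{i + 1}" for i in range(n_features)]
    table = FeatureTable(pd.DataFrame(cols, index=features))
    meta = SampleMetadata(
        pd.DataFrame(meta_rows).set_index("sample_id").rename_axis(None)
    )
    return table, meta


def gen_soil(truth: SimulationTruth, reps: int = 1,
             seed: int = 0) -> SoilTable:
    """Draw a soil table around the per-treatment means.

    Continuous indicators get truncated-Gaussian replicate noise
    (resampled until non-negative; exact means when SD = 0); the
    earthworm count indicator is negative-binomial with the configured
    dispersion.  With ``reps`` = 1, observation IDs are the treatment
    names; otherwise ``T#R#``.
    """
    rng = np.random.default_rng(seed)
    rows, ids = [], []
    nb_k = truth.earthworm_dispersion
    for t in truth.soil_means.index:
        mu = truth.soil_means.loc[t]
        sd = truth.soil_sds.loc[t]
        for r in range(1, reps + 1):
            row = {}
            for ind in truth.soil_means.columns:
                if ind == "earthworm_count":
                    m = float(mu[ind])
                    if sd[ind] == 0:
                        row[ind] = m
                    else:
                        p = nb_k / (nb_k + m)
                        row[ind] = float(rng.negative_binomial(nb_k, p))
                else:
                    val = rng.normal(mu[ind], sd[ind])
                    while val < 0:  # truncate positive-support indicators
                        val = rng.normal(mu[ind], sd[ind])
                    row[ind] = float(val)
            rows.append(row)
            ids.append(t if reps == 1 else f"{t}R{r}")
    return SoilTable(pd.DataFrame(rows, index=ids,
                                  columns=truth.soil_means.columns))


#: Within-block driver-echo correlations of the planted design (exact).
_PLANT_RHO_A = 0.95
_PLANT_RHO_B = 0.80


def _block_corr(rho: float) -> np.ndarray:
    # driver + two echoes sharing the driver's signal: corr(driver,
    # echo) = rho exactly, corr(echo, echo) = rho^2
    return np.array([[1.0, rho, rho],
                     [rho, 1.0, rho ** 2],
                     [rho, rho ** 2, 1.0]])


def gen_known_sqi_case(seed: int = 0, n_obs: int = 8):
    """Planted-factor soil table whose MDS and SQI ordering are known.

    Two orthogonal latent patterns (a linear trend and an exponential
    trend residualized against it) each drive a block of three
    indicators: a driver carrying the pattern exactly and two echoes
    equal to the driver plus a perturbation pattern built orthogonal to
    *everything* else (QR), so the indicator correlation matrix is
    exactly block diagonal: within block A corr(driver, echo) = 0.95,
    within block B 0.80, and zero across blocks.  Consequently the PCA
    retains exactly two components (eigenvalues ~2.87 and ~2.50, all
    others <= 0.36), the loading screen admits each block's members, and
    the correlation prune (|r| >= 0.6) keeps only each block's
    highest-loaded driver: the designed MDS is ``["driver_a",
    "driver_b"]``.  Both drivers attain their strict maximum at the
    last observation, which therefore attains the top SQI (all
    indicators more-is-better).

    The expected SQI ordering is computed analytically from the planted
    block eigenvalues and the sigmoid scoring formula — not by running
    the selection pipeline.

    Returns ``(soil, expected_mds, expected_order)``; ``expected_order``
    lists observation IDs from highest to lowest expected SQI.
    """
    if n_obs < 8:
        raise ValueError("planted design needs >= 8 observations")
    rng = np.random.default_rng(seed)
    k = np.arange(n_obs, dtype=float)
    lin = k - k.mean()
    expo = np.exp(k / 2.2)
    expo = expo - expo.mean()
    expo = expo - (expo @ lin) / (lin @ lin) * lin
    u1 = lin / lin.std(ddof=1)
    u2 = expo / expo.std(ddof=1)
    basis = np.column_stack([np.ones(n_obs), u1, u2,
                             rng.normal(size=(n_obs, 4))])
    q, _ = np.linalg.qr(basis)
    w = q[:, 3:7] * np.sqrt(n_obs - 1)  # unit-SD patterns, orthogonal to all
    t_a = np.sqrt(1.0 / _PLANT_RHO_A ** 2 - 1.0)
    t_b = np.sqrt(1.0 / _PLANT_RHO_B ** 2 - 1.0)
    da = 10.0 + 2.0 * u1
    db = 20.0 + 3.0 * u2
    df = pd.DataFrame(
        {
            "driver_a": da,
            "echo_a1": da + 2.0 * t_a * w[:, 0],
            "echo_a2": da + 2.0 * t_a * w[:, 1],
            "driver_b": db,
            "echo_b1": db + 3.0 * t_b * w[:, 2],
            "echo_b2": db + 3.0 * t_b * w[:, 3],
        },
        index=[f"O{i + 1}" for i in range(n_obs)],
    )
    expected_mds = ["driver_a", "driver_b"]
    # analytic ordering: weights from the planted block eigenvalues,
    # scores from the sigmoid evaluated directly on the planted drivers
    lam_a = float(np.linalg.eigvalsh(_block_corr(_PLANT_RHO_A)).max())
    lam_b = float(np.linalg.eigvalsh(_block_corr(_PLANT_RHO_B)).max())
    w_a = lam_a / (lam_a + lam_b)
    s_a = 1.0 / (1.0 + (da / da.mean()) ** -2.5)
    s_b = 1.0 / (1.0 + (db / db.mean()) ** -2.5)
    expected_sqi = pd.Series(w_a * s_a + (1.0 - w_a) * s_b, index=df.index)
    expected_order = list(expected_sqi.sort_values(ascending=False).index)
    return SoilTable(df), expected_mds, expected_order
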