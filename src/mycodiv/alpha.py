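"""Abundance-based alpha-diversity estimators.

Implements the within-sample indices reported for soil fungal
communities: observed richness, Shannon entropy (nats by default),
Gini-Simpson, the Chao1 and ACE non-parametric richness estimators and
Fisher's log-series alpha.  All estimators operate on a single sample's
count vector; :func:`alpha_table` applies them column-wise to a feature
table.

Branch conventions
------------------
* Chao1 uses the classic form S_obs + F1^2 / (2 F2) when doubletons are
  present, and the bias-corrected S_obs + F1 (F1 - 1) / 2 when F2 = 0.
* ACE falls back to Chao1 when every rare individual is a singleton
  (sample coverage estimate C_ace = 0); the fallback is flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .tables import FeatureTable

__all__ = [
    "observed_richness",
    "shannon",
    "simpson",
    "chao1",
    "ace",
    "fisher_alpha",
    "alpha_table",
]


def _counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    return c


def observed_richness(counts) -> int:
    """Number of features with count > 0."""
    return int(np.count_nonzero(_counts(counts) > 0))


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log by default).

    ``base`` converts to another logarithm base (e.g. 2 for bits).
    """
    c = _counts(counts)
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (probability two random reads differ)."""
    c = _counts(counts)
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = c / total
    return float(1.0 - (p ** 2).sum())


def chao1(counts) -> float:
    """Chao1 richness estimate from singleton/doubleton frequencies."""
    c = _counts(counts)
    s_obs = np.count_nonzero(c > 0)
    f1 = int(np.count_nonzero(c == 1))
    f2 = int(np.count_nonzero(c == 2))
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / 2.0)


def ace(counts, rare_cutoff: int = 10, flag: list | None = None) -> float:
    """Abundance-based Coverage Estimator of species richness.

    Species with counts <= ``rare_cutoff`` form the rare group used to
    estimate sample coverage.  If coverage C_ace is zero (all rare
    individuals are singletons) the estimate is undefined and Chao1 is
    returned instead; pass a list as ``flag`` to receive the string
    ``"chao1_fallback"`` when that happens.
    """
    c = _counts(counts)
    c = c[c > 0]
    rare = c[c <= rare_cutoff]
    s_abund = int(np.count_nonzero(c > rare_cutoff))
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int(np.count_nonzero(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        if flag is not None:
            flag.append("chao1_fallback")
        return chao1(counts)
    freqs = np.array([np.count_nonzero(rare == i)
                      for i in range(1, rare_cutoff + 1)])
    i = np.arange(1, rare_cutoff + 1)
    sum_term = float((i * (i - 1) * freqs).sum())
    if n_rare > 1:
        gamma2 = max(
            (s_rare / c_ace) * sum_term / (n_rare * (n_rare - 1.0)) - 1.0, 0.0
        )
    else:
        gamma2 = 0.0
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def fisher_alpha(s_obs: int, n: int, tol: float = 1e-10) -> float:
    """Fisher's log-series alpha: the root of S = alpha ln(1 + N / alpha).

    Solved by bracketed root finding to ``|S(alpha) - S| < tol``.
    Undefined when S_obs = 0 or S_obs >= N.
    """
    if s_obs <= 0 or n <= 0 or s_obs >= n:
        raise ValueError(
            f"Fisher's alpha requires 0 < S_obs < N, got S_obs={s_obs}, N={n}"
        )

    def f(a):
        return a * np.log1p(n / a) - s_obs

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket Fisher's alpha")
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def alpha_table(table: FeatureTable,
                indices: tuple = ("observed", "chao1", "ace", "shannon",
                                  "simpson", "fisher")) -> pd.DataFrame:
    """Per-sample alpha-diversity table (one row per sample).

    Fisher's alpha is NaN for samples where it is undefined (every read
    a distinct feature, or an empty sample).
    """
    if table.is_relative:
        raise ValueError("alpha estimators need raw counts")
    funcs = {
        "observed": lambda c: observed_richness(c),
        "chao1": chao1,
        "ace": ace,
        "shannon": shannon,
        "simpson": simpson,
    }
    rows = {}
    for sid in table.sample_ids:
        c = table.data[sid].to_numpy()
        row = {}
        for name in indices:
            if name == "fisher":
                s, n = observed_richness(c), int(c.sum())
                row[name] = (fisher_alpha(s, n)
                             if 0 < s < n else float("nan"))
            else:
                row[name] = funcs[name](c)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(indices)]
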