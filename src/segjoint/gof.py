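"""Goodness-of-fit of a fitted mixture, generation by generation.

A candidate model is judged adequate when, within each generation, the
probability-integral transform (PIT) of the data through the fitted
mixture CDF is indistinguishable from Uniform(0, 1).  Five statistics
are computed on the PIT values:

* ``U1^2``, ``U2^2``, ``U3^2`` — uniformity (Neyman smooth) components:
  squared normalized sample means of the first three shifted Legendre
  polynomials on [0, 1],

  ``pi_1(y) = sqrt(3) (2y - 1)``
  ``pi_2(y) = sqrt(5) (6y^2 - 6y + 1)``
  ``pi_3(y) = sqrt(7) (20y^3 - 30y^2 + 12y - 1)``

  each ``U_k^2 = (sum_i pi_k(y_i))^2 / n`` referred to chi-square(1);
  ``U1^2`` reduces to ``12 n (ybar - 1/2)^2``, a first-moment contrast,
  with ``U2^2``/``U3^2`` the second- and third-moment analogues.
* ``nW^2`` — the Cramér–von Mises statistic
  ``1/(12n) + sum_i (y_(i) - (2i-1)/(2n))^2`` with its asymptotic
  significance level (5% critical value 0.461).
* ``Dn`` — the Kolmogorov statistic
  ``max_i max(|i/n - y_(i)|, |y_(i) - (i-1)/n|)`` with the asymptotic
  Kolmogorov significance level.

The PIT uses the fitted parameter values, exact mixture CDF, no Monte
Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .genmodels import GENERATIONS
from .phenodata import SixGenDataset
from .seglik import FitResult

__all__ = [
    "GofRow",
    "mixture_cdf",
    "pit_transform",
    "uniformity_stats",
    "smirnov_nW2",
    "kolmogorov_Dn",
    "gof_generation",
    "gof_table",
    "count_significant",
]


@dataclass(frozen=True)
class GofRow:
    """Five fit statistics with probability / significance values."""

    generation: str
    U1sq: float
    U1sq_p: float
    U2sq: float
    U2sq_p: float
    U3sq: float
    U3sq_p: float
    nWsq: float
    nWsq_p: float
    Dn: float
    Dn_p: float

    def n_significant(self, alpha: float = 0.05) -> int:
        ps = (self.U1sq_p, self.U2sq_p, self.U3sq_p, self.nWsq_p, self.Dn_p)
        return int(sum(p < alpha for p in ps))


def mixture_cdf(x, weights, means, variances) -> np.ndarray:
    """CDF of a normal mixture, exact (sum of component CDFs)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    w = np.asarray(weights, dtype=float)
    mu = np.asarray(means, dtype=float)
    sd = np.sqrt(np.broadcast_to(np.asarray(variances, dtype=float), mu.shape))
    z = (x[:, None] - mu[None, :]) / sd[None, :]
    return special.ndtr(z) @ w


def pit_transform(values, weights, means, variances, sort: bool = False
                  ) -> np.ndarray:
    """Probability-integral transform of data through a fitted mixture."""
    y = mixture_cdf(values, weights, means, variances)
    return np.sort(y) if sort else y


def uniformity_stats(y) -> tuple[tuple[float, float], ...]:
    """Neyman smooth uniformity components U1^2, U2^2, U3^2.

    Returns three ``(statistic, probability)`` pairs; each statistic is
    asymptotically chi-square(1) under uniformity.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("PIT values must lie in [0, 1]")
    n = y.size
    p1 = np.sqrt(3.0) * (2.0 * y - 1.0)
    p2 = np.sqrt(5.0) * (6.0 * y * y - 6.0 * y + 1.0)
    p3 = np.sqrt(7.0) * (20.0 * y**3 - 30.0 * y * y + 12.0 * y - 1.0)
    out = []
    for pk in (p1, p2, p3):
        u = float(pk.sum() ** 2 / n)
        out.append((u, float(stats.chi2.sf(u, df=1))))
    return tuple(out)


def _cvm_limit_cdf(x: float, terms: int = 12) -> float:
    """Limiting CDF of n*W^2 (Smirnov's Bessel-K series)."""
    if x <= 0.0:
        return 0.0
    tot = 0.0
    for k in range(terms):
        q = (4.0 * k + 1.0) ** 2 / (16.0 * x)
        if q > 700.0:  # exp underflow; remaining terms negligible
            break
        term = (
            np.exp(special.gammaln(k + 0.5) - special.gammaln(k + 1.0))
            / (np.pi ** 1.5 * np.sqrt(x))
            * np.sqrt(4.0 * k + 1.0)
            * np.exp(-q)
            * special.kv(0.25, q)
        )
        tot += term
        if term < 1e-16 * max(tot, 1e-300):
            break
    return float(min(max(tot, 0.0), 1.0))


def smirnov_nW2(y) -> tuple[float, float]:
    """Cramér–von Mises ``nW^2`` against Uniform(0,1), asymptotic p."""
    y = np.sort(np.asarray(y, dtype=float))
    n = y.size
    i = np.arange(1, n + 1)
    w2 = 1.0 / (12.0 * n) + float(np.sum((y - (2.0 * i - 1.0) / (2.0 * n)) ** 2))
    p = 1.0 - _cvm_limit_cdf(w2)
    return w2, float(min(max(p, 0.0), 1.0))


def kolmogorov_Dn(y) -> tuple[float, float]:
    """Kolmogorov ``Dn`` against Uniform(0,1), asymptotic significance."""
    y = np.sort(np.asarray(y, dtype=float))
    n = y.size
    i = np.arange(1, n + 1)
    dn = float(np.max(np.maximum(i / n - y, y - (i - 1) / n)))
    p = float(special.kolmogorov(np.sqrt(n) * dn))
    return dn, p


def gof_generation(values, weights, means, variances,
                   generation: str = "") -> GofRow:
    """All five fit statistics for one generation's fitted mixture."""
    y = pit_transform(values, weights, means, variances)
    (u1, p1), (u2, p2), (u3, p3) = uniformity_stats(y)
    w2, pw = smirnov_nW2(y)
    dn, pd_ = kolmogorov_Dn(y)
    return GofRow(generation, u1, p1, u2, p2, u3, p3, w2, pw, dn, pd_)


def gof_table(fit: FitResult, dataset: SixGenDataset) -> pd.DataFrame:
    """Suitability-test table: one row per generation for one fit."""
    rows = []
    for g in GENERATIONS:
        row = gof_generation(
            dataset[g].values,
            fit.component_weights[g],
            fit.component_means[g],
            fit.component_variances[g],
            generation=g,
        )
        rows.append({
            "model": fit.model_name, "generation": g,
            "U1sq": row.U1sq, "U1sq_p": row.U1sq_p,
            "U2sq": row.U2sq, "U2sq_p": row.U2sq_p,
            "U3sq": row.U3sq, "U3sq_p": row.U3sq_p,
            "nWsq": row.nWsq, "nWsq_p": row.nWsq_p,
            "Dn": row.Dn, "Dn_p": row.Dn_p,
        })
    return pd.DataFrame(rows)


def count_significant(table: pd.DataFrame, alpha: float = 0.05) -> int:
    """Number of significant statistics (p < alpha) in a suitability table."""
    pcols = [c for c in table.columns if c.endswith("_p")]
    return int((table[pcols] < alpha).to_numpy().sum())
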