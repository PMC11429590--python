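"""First- and second-order genetic parameters of a fitted model.

First-order parameters are the effects on the mean scale: the overall
mean m, major-gene additive/dominance effects, the collective polygene
effects [d] and [h], and the polygene dominance degree [h]/[d].  They
are re-derived from the fitted component means by generalized least
squares on the component design matrices (weighted by effective
component sample sizes), which coincides with the EM estimates when the
design has full rank — both routes are computed and must agree.

Second-order parameters decompose, for each segregating generation g,
the sample phenotypic variance

    sigma2_p(g) = sigma2_e + sigma2_mg(g) + sigma2_pg(g)

where sigma2_e is the fitted environmental variance, sigma2_pg(g) the
fitted polygenic variance of g, and the major-gene variance
sigma2_mg(g) is obtained by subtraction (floored at zero, with a
warning when the raw value is negative), so the additivity identity
holds exactly.  Heritabilities are the corresponding percentages of
sigma2_p(g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmodels import SEGREGATING
from .phenodata import SixGenDataset
from .seglik import FitResult

__all__ = [
    "FirstOrderParams",
    "GenerationVariance",
    "VarianceComponents",
    "decompose",
    "dominance_degree",
    "first_order",
    "second_order",
    "first_order_table",
    "second_order_table",
]


@dataclass(frozen=True)
class FirstOrderParams:
    """Mean-scale genetic effects (trait units)."""

    model_name: str
    effects: dict[str, float]
    dominance_degree: float

    def __getitem__(self, name: str) -> float:
        return self.effects[name]


@dataclass(frozen=True)
class GenerationVariance:
    """Variance decomposition of one segregating generation."""

    generation: str
    sigma2_p: float
    sigma2_e: float
    sigma2_mg: float
    sigma2_pg: float
    h2_mg: float
    h2_pg: float
    h2_total: float
    env_fraction: float


@dataclass(frozen=True)
class VarianceComponents:
    """Second-order parameters for all segregating generations."""

    model_name: str
    sigma2_e: float
    generations: dict[str, GenerationVariance] = field(default_factory=dict)

    def __getitem__(self, generation: str) -> GenerationVariance:
        return self.generations[generation]


def dominance_degree(poly_h: float, poly_d: float) -> float:
    """Polygene dominance degree [h]/[d]; NaN when [d] = 0."""
    if poly_d == 0:
        return float("nan")
    return poly_h / poly_d


def first_order(fit: FitResult, atol: float = 1e-6) -> FirstOrderParams:
    """First-order genetic parameters via GLS on fitted component means.

    The stacked design rows of all generations are weighted by
    effective component sample sizes (summed posterior
    responsibilities) over component variances; the GLS solution must
    agree with the EM parameterization to ``atol`` (they are the same
    linear map when the design has full column rank).
    """
    if not fit.converged:
        warnings.warn(f"{fit.model_name}: fit did not converge; "
                      "first-order parameters may be unreliable",
                      RuntimeWarning)
    rows, y, w = [], [], []
    structure = fit.structure
    assert structure is not None, "fit carries no structure"
    for g, gm in structure.generations.items():
        A = gm.design_float()
        mu = fit.component_means[g]
        resp = fit.posterior_responsibilities.get(g)
        if resp is not None:
            neff = resp.sum(axis=0)
        else:
            neff = fit.n_per_generation[g] * fit.component_weights[g]
        rows.append(A)
        y.append(mu)
        w.append(neff / fit.component_variances[g])
    X = np.vstack(rows)
    yv = np.concatenate(y)
    wv = np.concatenate(w)
    sw = np.sqrt(np.maximum(wv, 1e-12))
    Xw = X * sw[:, None]
    rank = np.linalg.matrix_rank(Xw)
    p = X.shape[1]
    if rank < p:
        null = _null_space_params(Xw, structure.param_names)
        raise ValueError(
            "rank-deficient design: confounded parameters " + ", ".join(null))
    theta_gls, *_ = np.linalg.lstsq(Xw, yv * sw, rcond=None)
    if not np.allclose(theta_gls, fit.theta, atol=atol, rtol=0):
        raise AssertionError(
            "GLS re-estimate disagrees with EM parameterization: "
            f"{theta_gls} vs {fit.theta}")
    effects = dict(zip(structure.param_names, map(float, theta_gls)))
    dd = dominance_degree(effects.get("poly_h", 0.0),
                          effects.get("poly_d", 0.0))
    return FirstOrderParams(fit.model_name, effects, dd)


def _null_space_params(X: np.ndarray, names) -> list[str]:
    _, s, vt = np.linalg.svd(X)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    null_rows = vt[s.size - (s < tol).sum():] if s.size else vt
    involved = np.any(np.abs(null_rows) > 1e-8, axis=0) if null_rows.size \
        else np.zeros(len(names), bool)
    out = [n for n, flag in zip(names, involved) if flag]
    return out or list(names)


def decompose(generation: str, sigma2_p: float, sigma2_e: float,
              sigma2_pg: float) -> GenerationVariance:
    """Decompose one generation's phenotypic variance.

    The major-gene variance is obtained by subtraction,
    ``sigma2_mg = sigma2_p - sigma2_e - sigma2_pg`` (floored at zero
    with a warning), so the additivity identity holds exactly;
    heritabilities are percentages of ``sigma2_p``.
    """
    if sigma2_p <= 0:
        raise ValueError(f"{generation}: non-positive phenotypic variance, "
                         "heritability undefined")
    raw_mg = sigma2_p - sigma2_e - sigma2_pg
    if raw_mg < 0:
        warnings.warn(
            f"{generation}: major-gene variance {raw_mg:.3f} negative "
            "before flooring at 0", RuntimeWarning)
    s2mg = max(raw_mg, 0.0)
    return GenerationVariance(
        generation=generation,
        sigma2_p=sigma2_p,
        sigma2_e=sigma2_e,
        sigma2_mg=s2mg,
        sigma2_pg=sigma2_pg,
        h2_mg=100.0 * s2mg / sigma2_p,
        h2_pg=100.0 * sigma2_pg / sigma2_p,
        h2_total=100.0 * (s2mg + sigma2_pg) / sigma2_p,
        env_fraction=100.0 * sigma2_e / sigma2_p,
    )


def second_order(fit: FitResult, dataset: SixGenDataset) -> VarianceComponents:
    """Variance components and heritabilities per segregating generation."""
    gens = {}
    for g in SEGREGATING:
        s2p = float(np.var(dataset[g].values, ddof=1))
        gens[g] = decompose(g, s2p, fit.sigma2_e,
                            float(fit.sigma2_pg.get(g, 0.0)))
    return VarianceComponents(fit.model_name, fit.sigma2_e, gens)


def first_order_table(params: FirstOrderParams, round_to: int = 2
                      ) -> pd.DataFrame:
    rows = [{"parameter": k, "estimate": round(v, round_to)}
            for k, v in params.effects.items()]
    if "poly_d" in params.effects and "poly_h" in params.effects:
        rows.append({"parameter": "poly_h/poly_d",
                     "estimate": round(params.dominance_degree, round_to)})
    return pd.DataFrame(rows)


def second_order_table(vc: VarianceComponents, round_to: int = 2
                       ) -> pd.DataFrame:
    rows = []
    for g in SEGREGATING:
        gv = vc[g]
        rows.append({
            "generation": g,
            "sigma2_p": round(gv.sigma2_p, round_to),
            "sigma2_e": round(gv.sigma2_e, round_to),
            "sigma2_mg": round(gv.sigma2_mg, round_to),
            "sigma2_pg": round(gv.sigma2_pg, round_to),
            "h2_mg_percent": round(gv.h2_mg, round_to),
            "h2_pg_percent": round(gv.h2_pg, round_to),
            "h2_total_percent": round(gv.h2_total, round_to),
            "env_fraction_percent": round(gv.env_fraction, round_to),
        })
    return pd.DataFrame(rows)
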