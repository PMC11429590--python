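"""Joint maximum-likelihood fitting of mixed inheritance models.

The joint log-likelihood of a six-generation dataset under a model is
the sum over generations g and individuals x of
``log sum_c pi_gc N(x; mu_gc, v_g)``, with component means
``mu_g = A_g theta`` linear in the free effect parameters and
component variances ``v_g = sigma2_e`` in non-segregating generations
(and in all generations of pure major-gene models) or
``v_g = sigma2_e + sigma2_pg(g)`` in the segregating generations of
polygene-carrying models.

Maximization uses EM with conditional maximization steps (IECM):

* E-step: within-generation component responsibilities;
* CM-step 1: weighted least squares of responsibility-weighted data on
  the stacked component design matrices updates theta in closed form;
* CM-step 2: the variance block (sigma2_e, v_g) is maximized jointly in
  closed form under the constraints v_g >= sigma2_e >= floor, pooling a
  segregating generation with the P1/P2/F1 block whenever its
  unconstrained variance falls below sigma2_e (the sigma2_pg >= 0 floor).

Both CM steps are exact coordinate maximizers of the EM Q-function, so
the likelihood is non-decreasing at every iteration; this is asserted.
Mixture likelihoods are multimodal, so the fit is repeated from several
seeded starting points and the best solution kept.

Identifiability convention
--------------------------
In mixed models whose major loci carry only additive effects (e.g.
MX2-A-AD), flipping the sign of a locus effect while shifting the
polygenic additive effect, ``(d_i, [d]) -> (-d_i, [d] + 2 d_i)``,
permutes component means within every generation and leaves the joint
likelihood exactly unchanged; likewise relabelling the two loci.  The
reported solution is the canonical representative with loci ordered
``|d_a| >= |d_b|``, ``d_a >= 0`` (the allele from the high parent P1
increases the trait at the leading locus), and any remaining sign
ambiguity resolved in favour of the largest polygenic additive effect
(equivalently ``d_b <= 0``).  Every candidate relabelling is verified
to be an exact symmetry of the mixture before it is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Mapping

import numpy as np

from .genmodels import (
    GENERATIONS,
    SEGREGATING,
    EffectParams,
    MixtureStructure,
    ModelSpec,
    build_structure,
    get_model,
)
from .phenodata import SixGenDataset

__all__ = ["FitConfig", "FitResult", "joint_loglik", "fit", "fit_models"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitConfig:
    """EM/multi-start settings.

    ``tol`` is an absolute tolerance on the change in joint
    log-likelihood between iterations.  ``no_polygenic_variance`` forces
    sigma2_pg = 0 (all component variances equal sigma2_e), which makes
    single-component-per-generation models exactly weighted least
    squares.  ``var_floor_frac`` scales the lower variance bound
    relative to the pooled sample variance.
    """

    n_starts: int = 10
    max_iter: int = 2000
    tol: float = 1e-8
    seed: int = 0
    no_polygenic_variance: bool = False
    var_floor_frac: float = 1e-6
    jitter_scale: float = 0.5


@dataclass
class FitResult:
    """Outcome of one joint ML fit."""

    model_name: str
    param_names: tuple[str, ...]
    theta: np.ndarray
    estimates: EffectParams
    sigma2_e: float
    sigma2_pg: dict[str, float]
    component_weights: dict[str, np.ndarray]
    component_means: dict[str, np.ndarray]
    component_variances: dict[str, float]
    n_per_generation: dict[str, int]
    loglik: float
    aic: float
    n_iterations: int
    converged: bool
    loglik_path: np.ndarray
    posterior_responsibilities: dict[str, np.ndarray]
    pg_floor_active: dict[str, bool] = field(default_factory=dict)
    structure: MixtureStructure | None = None

    def to_jsonable(self) -> dict:
        return {
            "model": self.model_name,
            "estimates": {n: float(t) for n, t in zip(self.param_names, self.theta)},
            "sigma2_e": self.sigma2_e,
            "sigma2_pg": dict(self.sigma2_pg),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "pg_floor_active": dict(self.pg_floor_active),
        }


class _Prepared:
    """Flattened float views of data and structure for the EM loop.

    All generations are stacked into one length-N vector; component
    dimensions are padded to the largest component count with -inf
    log-weights, so the E-step is a handful of (N, Cmax) array
    operations.
    """

    def __init__(self, dataset: SixGenDataset, structure: MixtureStructure):
        self.structure = structure
        self.gens = list(GENERATIONS)
        self.n = {g: dataset[g].n for g in self.gens}
        self.N = sum(self.n.values())
        self.A = {g: structure.generations[g].design_float() for g in self.gens}
        self.C = {g: self.A[g].shape[0] for g in self.gens}
        self.Cmax = max(self.C.values())
        self.x_all = np.concatenate([dataset[g].values for g in self.gens])
        self.xsq_all = self.x_all * self.x_all
        self.slices = {}
        self.logw_mat = np.full((self.N, self.Cmax), -np.inf)
        start = 0
        for g in self.gens:
            sl = slice(start, start + self.n[g])
            self.slices[g] = sl
            w = structure.generations[g].weights_float()
            self.logw_mat[sl, : self.C[g]] = np.log(w)
            start += self.n[g]
        self.seg_var = [g for g in self.gens
                        if structure.generations[g].variance_key == "seg"]
        self.pooled_var = float(np.var(self.x_all))
        self._mu = np.zeros((self.N, self.Cmax))
        self._vrow = np.empty(self.N)

    def variances(self, s2e: float, v: Mapping[str, float]) -> dict[str, float]:
        return {g: (v[g] if g in self.seg_var else s2e) for g in self.gens}

    def estep(self, theta, var, want_resp=False):
        """Joint log-likelihood and per-component sufficient statistics."""
        mu_mat, vrow = self._mu, self._vrow
        for g in self.gens:
            sl = self.slices[g]
            mu_mat[sl, : self.C[g]] = self.A[g] @ theta
            vrow[sl] = var[g]
        z = self.x_all[:, None] - mu_mat
        logpdf = (self.logw_mat
                  - 0.5 * (_LOG2PI + np.log(vrow))[:, None]
                  - z * z / (2.0 * vrow)[:, None])
        mx = logpdf.max(axis=1)
        with np.errstate(invalid="ignore"):
            resp = np.exp(logpdf - mx[:, None])
        tot = resp.sum(axis=1)
        lse = mx + np.log(tot)
        resp /= tot[:, None]
        ll = float(lse.sum())
        stats = {}
        resp_out = {}
        for g in self.gens:
            sl, C = self.slices[g], self.C[g]
            r = resp[sl, :C]
            stats[g] = (r.sum(axis=0), r.T @ self.x_all[sl],
                        r.T @ self.xsq_all[sl])
            if want_resp:
                resp_out[g] = r.copy()
        return ll, stats, resp_out


def joint_loglik(dataset: SixGenDataset, structure: MixtureStructure,
                 params: EffectParams) -> float:
    """Joint log-likelihood at given parameter values (log-sum-exp safe)."""
    spec = structure.model
    theta = params.theta(spec)
    prep = _Prepared(dataset, structure)
    var = {g: params.component_variance(spec, g) for g in prep.gens}
    for v in var.values():
        if v <= 0:
            raise ValueError("component variances must be positive")
    ll, _, _ = prep.estep(theta, var)
    return ll


def _update_theta(prep: _Prepared, stats, var, p):
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    for g in prep.gens:
        A = prep.A[g]
        Nc, Sc, _ = stats[g]
        w = Nc / var[g]
        XtX += (A * w[:, None]).T @ A
        Xty += A.T @ (Sc / var[g])
    try:
        return np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(XtX, Xty, rcond=None)[0]


def _residual_ss(prep: _Prepared, stats, theta):
    S = {}
    for g in prep.gens:
        mu = prep.A[g] @ theta
        Nc, Sc, SSc = stats[g]
        S[g] = float(np.sum(SSc - 2.0 * mu * Sc + mu * mu * Nc))
    return S


def _update_variances(prep: _Prepared, S, floor, pooled_all: bool):
    """Exact joint maximizer of the variance block of the Q-function.

    With ``pooled_all`` every generation shares sigma2_e.  Otherwise
    sigma2_e comes from the non-segregating block and each segregating
    generation gets its own v_g, subject to v_g >= sigma2_e: a
    generation whose unconstrained variance falls below sigma2_e is
    pooled into the sigma2_e block (its polygenic variance hits the
    zero floor).
    """
    if pooled_all:
        s2e = max(sum(S.values()) / prep.N, floor)
        return s2e, {g: s2e for g in prep.seg_var}, {g: False
                                                     for g in prep.seg_var}
    nonseg = [g for g in prep.gens if g not in prep.seg_var]
    base_S = sum(S[g] for g in nonseg)
    base_n = sum(prep.n[g] for g in nonseg)
    active: set[str] = set()
    while True:
        s2e = (base_S + sum(S[g] for g in active)) / (
            base_n + sum(prep.n[g] for g in active))
        new_active = {g for g in prep.seg_var if S[g] / prep.n[g] < s2e}
        if new_active == active:
            break
        active = new_active
    s2e = max(s2e, floor)
    v = {g: (s2e if g in active else max(S[g] / prep.n[g], s2e))
         for g in prep.seg_var}
    return s2e, v, {g: g in active for g in prep.seg_var}


def _run_em(prep: _Prepared, theta0, s2e0, v0, config: FitConfig):
    spec = prep.structure.model
    p = len(prep.structure.param_names)
    floor = config.var_floor_frac * prep.pooled_var
    pooled_all = (not spec.has_polygene) or config.no_polygenic_variance
    theta = np.asarray(theta0, dtype=float).copy()
    s2e = max(float(s2e0), floor)
    if pooled_all:
        v = {g: s2e for g in prep.seg_var}
    else:
        v = {g: max(float(v0.get(g, s2e)), s2e) for g in prep.seg_var}
    path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        var = prep.variances(s2e, v)
        ll, stats, _ = prep.estep(theta, var)
        if ll < prev - 1e-8 * (1.0 + abs(prev)):
            raise RuntimeError(
                f"EM log-likelihood decreased ({prev} -> {ll}) for {spec.name}")
        path.append(ll)
        if np.isfinite(prev) and abs(ll - prev) < config.tol:
            converged = True
            break
        prev = ll
        theta = _update_theta(prep, stats, var, p)
        S = _residual_ss(prep, stats, theta)
        s2e, v, _ = _update_variances(prep, S, floor, pooled_all)
    var = prep.variances(s2e, v)
    ll, stats, resp = prep.estep(theta, var, want_resp=True)
    path.append(ll)
    _, _, floored = _update_variances(
        prep, _residual_ss(prep, stats, theta), floor, pooled_all)
    starving = [g for g in prep.gens
                if prep.C[g] > 1 and float(np.min(stats[g][0])) < 1.0]
    if starving:
        warnings.warn(
            f"{spec.name}: component with responsibility mass < 1 individual "
            f"in {starving}; variance floor in effect", RuntimeWarning)
    return theta, s2e, v, ll, it, converged, np.array(path), resp, floored


def _moment_start(prep: _Prepared, rng: np.random.Generator | None,
                  config: FitConfig):
    """Moment-based start: generation means regressed on mean design rows."""
    struct = prep.structure
    rows, ybar, wts = [], [], []
    for g in prep.gens:
        gm = struct.generations[g]
        rows.append(gm.weights_float() @ gm.design_float())
        ybar.append(float(np.mean(prep.x_all[prep.slices[g]])))
        wts.append(prep.n[g])
    X = np.asarray(rows)
    y = np.asarray(ybar)
    w = np.sqrt(np.asarray(wts, dtype=float))
    theta0, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    nonseg = [g for g in prep.gens if g not in prep.seg_var] or prep.gens
    s2e0 = float(np.mean(
        [np.var(prep.x_all[prep.slices[g]], ddof=1) for g in nonseg]))
    v0 = {g: float(np.var(prep.x_all[prep.slices[g]], ddof=1))
          for g in prep.seg_var}
    if rng is not None:
        scale = config.jitter_scale * np.sqrt(prep.pooled_var)
        theta0 = theta0 + rng.normal(0.0, scale, size=theta0.size)
        s2e0 *= float(np.exp(rng.normal(0.0, 0.5)))
        v0 = {g: val * float(np.exp(rng.normal(0.0, 0.5)))
              for g, val in v0.items()}
    return theta0, s2e0, v0


# ---------------------------------------------------------------------------
# canonical representative among exactly likelihood-equivalent relabellings

def _mixture_signature(structure: MixtureStructure, theta) -> list[np.ndarray]:
    """Sorted (mean, weight) pairs per generation — relabelling-invariant."""
    sig = []
    for g in GENERATIONS:
        gm = structure.generations[g]
        mu = gm.design_float() @ np.asarray(theta, dtype=float)
        w = gm.weights_float()
        order = np.lexsort((w, mu))
        sig.append(np.column_stack([mu[order], w[order]]))
    return sig


def _same_signature(a, b, atol=1e-8) -> bool:
    return all(x.shape == y.shape and np.allclose(x, y, atol=atol)
               for x, y in zip(a, b))


def _candidate_transforms(spec: ModelSpec, names: tuple[str, ...], theta):
    """Enumerate candidate relabellings: locus swap x per-locus sign flips."""
    tdict = dict(zip(names, theta))
    cands = []
    swaps = [False, True] if spec.major_gene_count == 2 else [False]
    additive_loci = []
    if spec.has_polygene and "poly_d" in tdict:
        for locus, dname in (("a", "d_a"), ("b", "d_b")):
            if dname in tdict and f"h_{locus}" not in tdict:
                additive_loci.append(dname)
    flip_sets = list(_iterproduct([1, -1], repeat=len(additive_loci)))
    for do_swap in swaps:
        base = dict(tdict)
        if do_swap:
            for x, y in (("d_a", "d_b"), ("h_a", "h_b"), ("j_ab", "j_ba")):
                if x in base and y in base:
                    base[x], base[y] = base[y], base[x]
        for signs in flip_sets:
            cand = dict(base)
            shift = 0.0
            for dname, s in zip(additive_loci, signs):
                if s < 0:
                    shift += 2.0 * cand[dname]
                    cand[dname] = -cand[dname]
            if shift:
                # EA-tied loci share one d; each tied locus contributes
                per_locus = 2 if spec.major_constraint == "EA" else 1
                cand["poly_d"] = cand["poly_d"] + shift * per_locus
            cands.append(np.array([cand[n] for n in names]))
    return cands


def _canonicalize(structure: MixtureStructure, theta) -> np.ndarray:
    """Pick the canonical representative among exact symmetries."""
    spec = structure.model
    names = structure.param_names
    ref = _mixture_signature(structure, theta)
    valid = [cand for cand in _candidate_transforms(spec, names, theta)
             if _same_signature(ref, _mixture_signature(structure, cand))]
    if not valid:
        return np.asarray(theta, dtype=float)

    idx = {n: i for i, n in enumerate(names)}

    def key(cand):
        da = cand[idx["d_a"]] if "d_a" in idx else 0.0
        db = cand[idx["d_b"]] if "d_b" in idx else 0.0
        pd_ = cand[idx["poly_d"]] if "poly_d" in idx else 0.0
        # ordered loci, leading effect non-negative, then favour polygene
        return (abs(db) > abs(da) + 1e-12, da < -1e-12, -pd_)

    return min(valid, key=key)


def fit(dataset: SixGenDataset, spec: ModelSpec | str,
        config: FitConfig | None = None) -> FitResult:
    """Fit one model to a six-generation dataset by multi-start IECM.

    Returns the best solution over ``config.n_starts`` seeded starting
    points; exact ties in log-likelihood are broken by the
    lexicographically smallest ``|theta|``.  Non-convergence within
    ``max_iter`` iterations is reported through ``converged=False``,
    not raised.  The returned solution is the canonical representative
    described in the module docstring.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    config = config or FitConfig()
    structure = build_structure(spec)
    prep = _Prepared(dataset, structure)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    best = None
    for start in range(config.n_starts):
        theta0, s2e0, v0 = _moment_start(
            prep, rng if start > 0 else None, config)
        try:
            sol = _run_em(prep, theta0, s2e0, v0, config)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            continue
        if best is None:
            best = sol
            continue
        ll_new, ll_best = sol[3], best[3]
        if ll_new > ll_best + 1e-6:
            best = sol
        elif abs(ll_new - ll_best) <= 1e-6:
            if tuple(np.abs(sol[0])) < tuple(np.abs(best[0])):
                best = sol
    assert best is not None, "all EM starts failed"
    theta, s2e, v, ll, n_iter, converged, path, _, floored = best
    theta = _canonicalize(structure, theta)
    var = prep.variances(s2e, v)
    ll, _, resp = prep.estep(theta, var, want_resp=True)
    sigma2_pg = {g: max(v.get(g, s2e) - s2e, 0.0) for g in SEGREGATING} \
        if (spec.has_polygene and not config.no_polygenic_variance) \
        else {g: 0.0 for g in SEGREGATING}
    estimates = _theta_to_effects(spec, structure.param_names, theta, s2e,
                                  sigma2_pg)
    return FitResult(
        model_name=spec.name,
        param_names=structure.param_names,
        theta=np.asarray(theta, dtype=float),
        estimates=estimates,
        sigma2_e=float(s2e),
        sigma2_pg={g: float(sigma2_pg[g]) for g in SEGREGATING},
        component_weights={g: structure.generations[g].weights_float()
                           for g in prep.gens},
        component_means=structure.component_means(theta),
        component_variances={g: float(var[g]) for g in prep.gens},
        n_per_generation={g: prep.n[g] for g in prep.gens},
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * spec.k),
        n_iterations=int(n_iter),
        converged=bool(converged),
        loglik_path=path,
        posterior_responsibilities={
            g: r for g, r in resp.items() if r.shape[1] > 1},
        pg_floor_active={g: bool(floored.get(g, False)) for g in SEGREGATING},
        structure=structure,
    )


def _theta_to_effects(spec: ModelSpec, names, theta, s2e, sigma2_pg):
    sub = spec.substitution()
    tdict = dict(zip(names, theta))
    full = {p: float(sum(float(c) * tdict[f] for f, c in sub[p].items()))
            for p in sub}
    return EffectParams(**full, sigma2_e=float(s2e),
                        sigma2_pg={g: float(sigma2_pg[g]) for g in SEGREGATING})


def fit_models(dataset: SixGenDataset, models=None,
               config: FitConfig | None = None) -> dict[str, FitResult]:
    """Fit a set of models (default: all 24) and return name -> result."""
    from .genmodels import MODEL_NAMES
    names = list(models) if models is not None else list(MODEL_NAMES)
    return {name: fit(dataset, name, config) for name in names}
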