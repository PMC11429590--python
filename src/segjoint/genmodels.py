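"""Registry of mixed major-gene plus polygene inheritance models.

A six-generation cross (P1, P2, F1, F2, BC1P1, BC1P2) segregating for a
quantitative trait is modelled as, per generation, a finite mixture of
normal distributions.  Mixture components correspond to major-locus
genotype classes with Mendelian frequencies; component means are linear
functions of genetic effect parameters; polygenic background enters as a
generation-specific mean shift plus extra within-component variance in
the segregating generations.

Each of the 24 catalogued models is a constraint set applied to one
generative rule, never a hand-written table:

* enumerate major-locus genotype classes per generation with Mendelian
  frequencies (F2 per locus 1:2:1, BC1P1 1 AA : 1 Aa, BC1P2 1 Aa : 1 aa,
  free recombination between loci);
* the genotypic value of a class with locus codes ``u, v in {+1, 0, -1}``
  is ``u*d_a + (1-|u|)*h_a + v*d_b + (1-|v|)*h_b`` plus the digenic
  epistatic terms ``u*v*i_ab + u*(1-|v|)*j_ab + (1-|u|)*v*j_ba +
  (1-|u|)*(1-|v|)*l_ab``;
* the polygene shift in generation g is ``alpha*[d] + beta*[h]`` (and
  for epistatic polygene models additionally ``alpha^2*[i] +
  alpha*beta*[j] + beta^2*[l]``) with the classical generation-mean
  coefficients (alpha, beta): P1 (1, 0), P2 (-1, 0), F1 (0, 1),
  F2 (0, 1/2), BC1P1 (1/2, 1/2), BC1P2 (-1/2, 1/2).

All weights and design coefficients are exact rationals; components
whose mean rows coincide exactly are merged and their weights summed.

Free-parameter counts follow the convention of the segregation-analysis
literature: every model fits one environmental variance sigma2_e (the
within-component variance of P1, P2, F1), and models with a polygene
part additionally fit one free polygenic variance per segregating
generation (F2, BC1P1, BC1P2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from itertools import product
from typing import Mapping

import numpy as np

__all__ = [
    "GENERATIONS",
    "SEGREGATING",
    "FULL_MEAN_PARAMS",
    "MODEL_NAMES",
    "EffectParams",
    "ModelSpec",
    "GenerationMixture",
    "MixtureStructure",
    "get_model",
    "build_structure",
    "count_free_parameters",
    "registry_to_json",
]

GENERATIONS: tuple[str, ...] = ("P1", "P2", "F1", "F2", "BC1P1", "BC1P2")
#: generations in which major loci and polygenes segregate
SEGREGATING: tuple[str, ...] = ("F2", "BC1P1", "BC1P2")

#: canonical ordering of the unconstrained mean-parameter vector
FULL_MEAN_PARAMS: tuple[str, ...] = (
    "m",
    "d_a", "h_a", "d_b", "h_b",
    "i_ab", "j_ab", "j_ba", "l_ab",
    "poly_d", "poly_h", "poly_i", "poly_j", "poly_l",
)

# per-locus genotype code distribution by generation (code: frequency)
_LOCUS_DIST: dict[str, dict[int, Fraction]] = {
    "P1": {+1: Fraction(1)},
    "P2": {-1: Fraction(1)},
    "F1": {0: Fraction(1)},
    "F2": {+1: Fraction(1, 4), 0: Fraction(1, 2), -1: Fraction(1, 4)},
    "BC1P1": {+1: Fraction(1, 2), 0: Fraction(1, 2)},
    "BC1P2": {0: Fraction(1, 2), -1: Fraction(1, 2)},
}

# polygene generation-mean coefficients (alpha on [d], beta on [h])
_POLY_AB: dict[str, tuple[Fraction, Fraction]] = {
    "P1": (Fraction(1), Fraction(0)),
    "P2": (Fraction(-1), Fraction(0)),
    "F1": (Fraction(0), Fraction(1)),
    "F2": (Fraction(0), Fraction(1, 2)),
    "BC1P1": (Fraction(1, 2), Fraction(1, 2)),
    "BC1P2": (Fraction(-1, 2), Fraction(1, 2)),
}


@dataclass(frozen=True)
class ModelSpec:
    """One entry of the 24-model catalogue.

    ``name`` follows the grammar ``<major part>-<major constraint>[-<polygene
    constraint>]``: ``1MG``/``2MG`` are pure major-gene models, ``PG`` pure
    polygene, ``MX1``/``MX2`` mixed.  Major-effect constraint codes:

    ``AD``   additive and dominance effects free, no epistasis
    ``A``    additive only
    ``ADI``  additive, dominance and digenic epistasis all free
    ``EA``   equal additive effects across loci, no dominance
    ``EAD``  a single effect shared by all additive and dominance terms
             (for one locus: complete dominance, h = d)
    ``CD``   complete dominance per locus (h_i = d_i)
    ``NCD``  negative complete dominance (h_i = -d_i)

    Polygene constraint ``AD`` frees [d] and [h]; ``ADI`` additionally frees
    the collective epistatic shifts [i], [j], [l].
    """

    name: str
    major_gene_count: int  # 0, 1 or 2
    major_constraint: str | None
    polygene_constraint: str | None

    @property
    def has_polygene(self) -> bool:
        return self.polygene_constraint is not None

    @property
    def free_mean_params(self) -> tuple[str, ...]:
        names: list[str] = ["m"]
        mc, nmg = self.major_constraint, self.major_gene_count
        if nmg:
            if mc == "ADI":
                names += ["d_a", "h_a", "d_b", "h_b", "i_ab", "j_ab", "j_ba", "l_ab"]
            elif mc == "AD":
                names += ["d_a", "h_a"] + (["d_b", "h_b"] if nmg == 2 else [])
            elif mc in ("A", "CD", "NCD"):
                names += ["d_a"] + (["d_b"] if nmg == 2 else [])
                if mc == "NCD" and nmg == 2:  # not in the catalogue, kept coherent
                    pass
            elif mc in ("EA", "EAD"):
                names += ["d_a"]
            else:  # pragma: no cover - registry guards this
                raise ValueError(f"unknown major constraint {mc!r}")
        pc = self.polygene_constraint
        if pc == "AD":
            names += ["poly_d", "poly_h"]
        elif pc == "ADI":
            names += ["poly_d", "poly_h", "poly_i", "poly_j", "poly_l"]
        elif pc is not None:  # pragma: no cover
            raise ValueError(f"unknown polygene constraint {pc!r}")
        return tuple(names)

    @property
    def k(self) -> int:
        """Free parameters entering AIC: means + sigma2_e (+ 3 sigma2_pg)."""
        return len(self.free_mean_params) + 1 + (3 if self.has_polygene else 0)

    def substitution(self) -> dict[str, dict[str, Fraction]]:
        """Map every unconstrained mean parameter to free parameters.

        Returns, for each name in :data:`FULL_MEAN_PARAMS`, the exact
        linear combination of the model's free parameters it equals
        (empty mapping = fixed at zero).
        """
        free = set(self.free_mean_params)
        sub: dict[str, dict[str, Fraction]] = {p: {} for p in FULL_MEAN_PARAMS}
        for p in free:
            sub[p] = {p: Fraction(1)}
        mc, nmg = self.major_constraint, self.major_gene_count
        if nmg == 2 and mc == "EA":
            sub["d_b"] = {"d_a": Fraction(1)}
        elif mc == "CD":
            sub["h_a"] = {"d_a": Fraction(1)}
            if nmg == 2:
                sub["h_b"] = {"d_b": Fraction(1)}
        elif mc == "NCD":
            sub["h_a"] = {"d_a": Fraction(-1)}
        elif mc == "EAD":
            sub["h_a"] = {"d_a": Fraction(1)}
            if nmg == 2:
                sub["d_b"] = {"d_a": Fraction(1)}
                sub["h_b"] = {"d_a": Fraction(1)}
        return sub


def _catalogue() -> dict[str, ModelSpec]:
    entries = [
        ("1MG-AD", 1, "AD", None),
        ("1MG-A", 1, "A", None),
        ("1MG-EAD", 1, "EAD", None),
        ("1MG-NCD", 1, "NCD", None),
        ("2MG-ADI", 2, "ADI", None),
        ("2MG-AD", 2, "AD", None),
        ("2MG-A", 2, "A", None),
        ("2MG-EA", 2, "EA", None),
        ("2MG-CD", 2, "CD", None),
        ("2MG-EAD", 2, "EAD", None),
        ("PG-ADI", 0, None, "ADI"),
        ("PG-AD", 0, None, "AD"),
        ("MX1-AD-ADI", 1, "AD", "ADI"),
        ("MX1-AD-AD", 1, "AD", "AD"),
        ("MX1-A-AD", 1, "A", "AD"),
        ("MX1-EAD-AD", 1, "EAD", "AD"),
        ("MX1-NCD-AD", 1, "NCD", "AD"),
        ("MX2-ADI-ADI", 2, "ADI", "ADI"),
        ("MX2-ADI-AD", 2, "ADI", "AD"),
        ("MX2-AD-AD", 2, "AD", "AD"),
        ("MX2-A-AD", 2, "A", "AD"),
        ("MX2-EA-AD", 2, "EA", "AD"),
        ("MX2-CD-AD", 2, "CD", "AD"),
        ("MX2-EAD-AD", 2, "EAD", "AD"),
    ]
    return {name: ModelSpec(name, n, mc, pc) for name, n, mc, pc in entries}


MODEL_REGISTRY: dict[str, ModelSpec] = _catalogue()
MODEL_NAMES: tuple[str, ...] = tuple(MODEL_REGISTRY)


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; valid codes: {', '.join(MODEL_NAMES)}"
        ) from None


def count_free_parameters(spec: ModelSpec | str) -> int:
    if isinstance(spec, str):
        spec = get_model(spec)
    return spec.k


@dataclass(frozen=True)
class GenerationMixture:
    """Mixture layout of one generation under one model.

    ``design[c]`` gives the exact coefficients of the free mean
    parameters for component ``c``; ``weights`` are Mendelian mixing
    proportions; ``variance_key`` is ``"env"`` when the component
    variance is sigma2_e and ``"seg"`` when it is
    sigma2_e + sigma2_pg(generation).
    """

    generation: str
    weights: tuple[Fraction, ...]
    design: tuple[tuple[Fraction, ...], ...]
    variance_key: str

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def weights_float(self) -> np.ndarray:
        return np.array([float(w) for w in self.weights])

    def design_float(self) -> np.ndarray:
        return np.array([[float(a) for a in row] for row in self.design])


@dataclass(frozen=True)
class MixtureStructure:
    """Per-generation mixture layout of a model over the whole design."""

    model: ModelSpec
    param_names: tuple[str, ...]
    generations: Mapping[str, GenerationMixture]

    def component_means(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        return {g: gm.design_float() @ theta for g, gm in self.generations.items()}

    def to_jsonable(self) -> dict:
        return {
            "model": self.model.name,
            "k": self.model.k,
            "free_mean_params": list(self.param_names),
            "generations": {
                g: {
                    "weights": [str(w) for w in gm.weights],
                    "design": [[str(a) for a in row] for row in gm.design],
                    "variance": (
                        "sigma2_e"
                        if gm.variance_key == "env"
                        else f"sigma2_e + sigma2_pg({g})"
                    ),
                }
                for g, gm in self.generations.items()
            },
        }


def _full_row(genotype: tuple[int, ...], alpha: Fraction, beta: Fraction,
              nmg: int, has_poly: bool) -> dict[str, Fraction]:
    """Coefficients of the unconstrained mean parameters for one class."""
    row = {p: Fraction(0) for p in FULL_MEAN_PARAMS}
    row["m"] = Fraction(1)
    if nmg >= 1:
        u = genotype[0]
        row["d_a"] = Fraction(u)
        row["h_a"] = Fraction(1 - abs(u))
    if nmg == 2:
        u, v = genotype
        row["d_b"] = Fraction(v)
        row["h_b"] = Fraction(1 - abs(v))
        row["i_ab"] = Fraction(u * v)
        row["j_ab"] = Fraction(u * (1 - abs(v)))
        row["j_ba"] = Fraction((1 - abs(u)) * v)
        row["l_ab"] = Fraction((1 - abs(u)) * (1 - abs(v)))
    if has_poly:
        row["poly_d"] = alpha
        row["poly_h"] = beta
        row["poly_i"] = alpha * alpha
        row["poly_j"] = alpha * beta
        row["poly_l"] = beta * beta
    return row


def build_structure(spec: ModelSpec | str) -> MixtureStructure:
    """Construct the exact mixture structure of a catalogued model.

    Components with identical (exact rational) mean rows are merged and
    their Mendelian weights summed, so the returned component count is
    the number of *distinct* genotypic-value classes.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    sub = spec.substitution()
    free = spec.free_mean_params
    gens: dict[str, GenerationMixture] = {}
    for g in GENERATIONS:
        alpha, beta = _POLY_AB[g]
        dist = _LOCUS_DIST[g]
        genotypes: list[tuple[tuple[int, ...], Fraction]] = []
        if spec.major_gene_count == 0:
            genotypes = [((), Fraction(1))]
        else:
            for combo in product(dist.items(), repeat=spec.major_gene_count):
                codes = tuple(c for c, _ in combo)
                w = Fraction(1)
                for _, f in combo:
                    w *= f
                genotypes.append((codes, w))
        merged: dict[tuple[Fraction, ...], Fraction] = {}
        for codes, w in genotypes:
            full = _full_row(codes, alpha, beta, spec.major_gene_count,
                             spec.has_polygene)
            reduced = tuple(
                sum((coef * full[p] for p in FULL_MEAN_PARAMS
                     for fname, coef in sub[p].items() if fname == f),
                    Fraction(0))
                for f in free
            )
            merged[reduced] = merged.get(reduced, Fraction(0)) + w
        rows = sorted(merged.items(), key=lambda kv: kv[0], reverse=True)
        variance_key = "seg" if (g in SEGREGATING and spec.has_polygene) else "env"
        gens[g] = GenerationMixture(
            generation=g,
            weights=tuple(w for _, w in rows),
            design=tuple(r for r, _ in rows),
            variance_key=variance_key,
        )
        assert sum(gens[g].weights) == 1
    return MixtureStructure(model=spec, param_names=free, generations=gens)


@dataclass
class EffectParams:
    """Genetic effect parameters on the trait scale (mg/100 g).

    ``m`` is the overall mean ("mean of graduation"); ``d_a``/``d_b``
    and ``h_a``/``h_b`` the additive and dominance effects of the two
    major genes; ``i_ab``/``j_ab``/``j_ba``/``l_ab`` digenic epistasis;
    ``poly_d``/``poly_h`` the collective additive/dominance polygene
    effects ([d], [h]); ``poly_i``/``poly_j``/``poly_l`` collective
    polygenic epistasis.  ``sigma2_e`` is the environmental variance and
    ``sigma2_pg`` maps each segregating generation to its polygenic
    variance (both in squared trait units).
    """

    m: float = 0.0
    d_a: float = 0.0
    h_a: float = 0.0
    d_b: float = 0.0
    h_b: float = 0.0
    i_ab: float = 0.0
    j_ab: float = 0.0
    j_ba: float = 0.0
    l_ab: float = 0.0
    poly_d: float = 0.0
    poly_h: float = 0.0
    poly_i: float = 0.0
    poly_j: float = 0.0
    poly_l: float = 0.0
    sigma2_e: float = 1.0
    sigma2_pg: dict[str, float] = field(
        default_factory=lambda: {g: 0.0 for g in SEGREGATING})

    def mean_vector(self) -> dict[str, float]:
        return {p: float(getattr(self, p)) for p in FULL_MEAN_PARAMS}

    def theta(self, spec: ModelSpec) -> np.ndarray:
        """Free mean-parameter vector under ``spec``; validates constraints."""
        self.validate(spec)
        return np.array([getattr(self, p) for p in spec.free_mean_params])

    def validate(self, spec: ModelSpec, atol: float = 1e-9) -> None:
        """Check that every constrained parameter equals its implied value."""
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be > 0")
        for g, v in self.sigma2_pg.items():
            if v < 0:
                raise ValueError(f"sigma2_pg[{g}] must be >= 0")
        sub = spec.substitution()
        full = self.mean_vector()
        for p in FULL_MEAN_PARAMS:
            implied = sum(float(c) * full[f] for f, c in sub[p].items())
            if abs(full[p] - implied) > atol:
                raise ValueError(
                    f"parameter {p}={full[p]} violates the {spec.name} "
                    f"constraint (implied value {implied})"
                )

    def component_variance(self, spec: ModelSpec, generation: str) -> float:
        if generation in SEGREGATING and spec.has_polygene:
            return self.sigma2_e + self.sigma2_pg.get(generation, 0.0)
        return self.sigma2_e

    def with_updates(self, **kwargs) -> "EffectParams":
        return replace(self, **kwargs)


def registry_to_json(path=None) -> str:
    """Serialize all 24 mixture structures to JSON for external audit."""
    payload = {name: build_structure(name).to_jsonable() for name in MODEL_NAMES}
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
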