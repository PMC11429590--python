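"""Forward simulation of six-generation phenotypes under a catalogued model.

For each generation, individuals are assigned a mixture component with
the model's Mendelian probabilities and a phenotype drawn from the
component normal distribution.  Each generation uses an independent RNG
substream derived from the master seed, so enlarging or dropping one
generation never perturbs the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .genmodels import (
    GENERATIONS,
    SEGREGATING,
    EffectParams,
    build_structure,
    get_model,
)
from .phenodata import GenerationSample, SixGenDataset

__all__ = ["SimConfig", "simulate", "analytic_moments", "load_sim_config",
           "cross_config"]


@dataclass(frozen=True)
class SimConfig:
    """Generating model, effect parameters, sample sizes and seed."""

    model_name: str
    params: EffectParams
    n_per_generation: dict[str, int]
    seed: int = 0
    cross_id: str = "sim"

    def __post_init__(self):
        spec = get_model(self.model_name)
        self.params.validate(spec)
        for g in GENERATIONS:
            n = self.n_per_generation.get(g, 0)
            if n < 2:
                raise ValueError(f"n_per_generation[{g}] must be >= 2, got {n}")

    def with_seed(self, seed: int) -> "SimConfig":
        return SimConfig(self.model_name, self.params,
                         dict(self.n_per_generation), seed, self.cross_id)

    def with_sizes(self, n: int | dict[str, int]) -> "SimConfig":
        sizes = {g: n for g in GENERATIONS} if isinstance(n, int) else dict(n)
        return SimConfig(self.model_name, self.params, sizes, self.seed,
                         self.cross_id)


def _gen_rng(seed: int, generation: str) -> np.random.Generator:
    idx = GENERATIONS.index(generation)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(idx,)))


def simulate(config: SimConfig, return_components: bool = False):
    """Draw a six-generation dataset; deterministic given the seed.

    With ``return_components`` also returns, per generation, the
    component index assigned to each individual (useful for checking
    Mendelian frequencies).
    """
    spec = get_model(config.model_name)
    structure = build_structure(spec)
    samples = {}
    labels: dict[str, np.ndarray] = {}
    for g in GENERATIONS:
        gm = structure.generations[g]
        theta = config.params.theta(spec)
        means = gm.design_float() @ theta
        var = config.params.component_variance(spec, g)
        rng = _gen_rng(config.seed, g)
        n = config.n_per_generation[g]
        comp = rng.choice(gm.n_components, size=n, p=gm.weights_float())
        values = means[comp] + rng.standard_normal(n) * np.sqrt(var)
        samples[g] = GenerationSample(g, values, config.cross_id)
        labels[g] = comp
    ds = SixGenDataset(config.cross_id, samples)
    return (ds, labels) if return_components else ds


def analytic_moments(config: SimConfig, generation: str) -> tuple[float, float]:
    """Exact mean and variance of a generation's mixture distribution."""
    spec = get_model(config.model_name)
    structure = build_structure(spec)
    gm = structure.generations[generation]
    w = gm.weights_float()
    mu = gm.design_float() @ config.params.theta(spec)
    var = config.params.component_variance(spec, generation)
    mean = float(w @ mu)
    total_var = float(w @ (mu - mean) ** 2 + var)
    return mean, total_var


def _config_from_dict(payload: dict) -> SimConfig:
    params = dict(payload["params"])
    pg = params.pop("sigma2_pg", {}) or {}
    sigma2_pg = {g: float(pg.get(g, 0.0)) for g in SEGREGATING}
    ep = EffectParams(**params, sigma2_pg=sigma2_pg)
    return SimConfig(
        model_name=payload["model"],
        params=ep,
        n_per_generation={g: int(v)
                          for g, v in payload["n_per_generation"].items()},
        seed=int(payload.get("seed", 0)),
        cross_id=str(payload.get("cross_id", "sim")),
    )


def load_sim_config(path) -> SimConfig:
    """Load a simulation configuration from a JSON file."""
    with open(path) as fh:
        return _config_from_dict(json.load(fh))


def cross_config(cross: str, seed: int = 0) -> SimConfig:
    """Bundled simulation preset for cross ``"A"`` or ``"B"``.

    The presets encode the published fitted parameters of the two
    rapeseed vitamin-C crosses (two additive major genes plus
    additive-dominance polygenes) with the published generation sample
    sizes.
    """
    name = f"cross{cross.upper()}.json"
    ref = resources.files("segjoint").joinpath("configs", name)
    with ref.open() as fh:
        cfg = _config_from_dict(json.load(fh))
    return cfg.with_seed(seed)
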