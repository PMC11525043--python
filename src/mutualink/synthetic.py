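"""Synthetic bipartite communities with a known mutualistic network.

The generator emulates the structure of the field data the association
methods are meant for: two guilds sampled over a few dozen grassland
sites (plants as percent cover, butterflies as pooled transect counts), a
sparse literature-style interaction matrix with ordinal strengths, a
flower-availability matrix, and a flower-visitation count table.  The
defining knob is ``coupling`` (kappa): the degree to which a butterfly's
occupancy tracks the presence of its partner plants.  At kappa = 0 the two
guilds are placed independently, so every method's detections among
non-links are pure false positives and calibration can be checked; at
kappa > 0 interacting pairs aggregate spatially and sensitivity should
rise.

All draws flow from ``config.seed``; identical configs give identical
communities, including the delimited-text files written from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import (ALB_SCALE, BUTTERFLY, FLOWER, PLANT, InteractionMatrix,
                        OccurrenceData)

__all__ = [
    "SyntheticCommunityConfig",
    "SyntheticCommunity",
    "generate_truth",
    "generate_occupancy",
    "generate_abundance",
    "generate_flowers",
    "generate_visits",
    "generate_community",
]

#: Default distribution over positive strength codes: literature networks
#: carry many singleton records and few "paramount importance" partners.
DEFAULT_STRENGTH_WEIGHTS = {0.2: 0.40, 0.4: 0.20, 0.6: 0.20, 0.8: 0.10, 1.0: 0.10}


@dataclass(frozen=True)
class SyntheticCommunityConfig:
    """All generator parameters.

    Defaults mirror the shape of the target field data at desk-test scale:
    ~60 sites per region (regions span roughly 40-90), guilds of 50 plants
    and 20 butterflies, network connectance 0.12 (empirical grassland
    plant-butterfly networks run ~0.12-0.20), the six-level ordinal
    strength scale, and moderately sparse occupancy (Beta(2, 4) species
    baseline, mean 1/3 of sites).
    """

    n_sites: int = 60
    n_plants: int = 50
    n_butterflies: int = 20
    connectance_target: float = 0.12
    strength_scale: tuple[float, ...] = ALB_SCALE
    strength_weights: Mapping[float, float] | None = None
    occupancy_alpha: float = 2.0
    occupancy_beta: float = 4.0
    #: kappa >= 0, strength of interaction-driven aggregation of butterflies
    #: on their partner plants (0 = independent guilds).
    coupling: float = 1.0
    symmetric_coupling: bool = False
    #: negative-binomial shape of butterfly counts / log-sd of plant cover.
    abundance_dispersion: float = 1.5
    #: multiplicative log-normal noise sd on flowering units.
    flower_noise: float = 0.5
    #: probability a locally present plant shows no open flowers at all.
    flower_dropout: float = 0.15
    #: expected visits per unit strength per co-occupied site.
    visit_rate: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.connectance_target <= 1:
            raise ValueError("connectance_target must lie in [0, 1]")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        for name in ("flower_dropout",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.n_sites, self.n_plants, self.n_butterflies) < 1:
            raise ValueError("community dimensions must be positive")

    def weights(self) -> dict[float, float]:
        w = dict(self.strength_weights) if self.strength_weights else {
            k: v for k, v in DEFAULT_STRENGTH_WEIGHTS.items() if k in self.strength_scale}
        total = sum(w.values())
        return {k: v / total for k, v in w.items()}

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible stream per generation stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:03d}" for i in range(n)]


def generate_truth(config: SyntheticCommunityConfig) -> InteractionMatrix:
    """Known interaction network: each pair is a link independently with
    probability ``connectance_target``; strengths follow the configured
    distribution over the positive scale codes."""
    rng = config.rng(1)
    shape = (config.n_plants, config.n_butterflies)
    links = rng.random(shape) < config.connectance_target
    weights = config.weights()
    codes = np.array(list(weights))
    probs = np.array([weights[c] for c in codes])
    strengths = rng.choice(codes, size=shape, p=probs)
    return InteractionMatrix(plants=_ids("P", config.n_plants),
                             butterflies=_ids("B", config.n_butterflies),
                             strength=np.where(links, strengths, 0.0),
                             scale=config.strength_scale)


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def generate_occupancy(config: SyntheticCommunityConfig, truth: InteractionMatrix,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Sites x species presence matrices (plants, butterflies).

    Plants are placed independently with per-species baseline probabilities
    drawn from Beta(occupancy_alpha, occupancy_beta).  Butterfly presence
    at a site follows a logistic model whose linear predictor adds
    ``coupling * sum_p strength(p, b) * presence(s, p)`` to the species
    baseline logit, so interacting pairs aggregate when coupling > 0.  With
    ``symmetric_coupling`` the plants are then re-drawn with the analogous
    term from butterfly presences (nectar-resource tracking both ways).
    """
    rng = config.rng(2)
    S = config.n_sites
    base_p = rng.beta(config.occupancy_alpha, config.occupancy_beta, config.n_plants)
    base_b = rng.beta(config.occupancy_alpha, config.occupancy_beta, config.n_butterflies)
    plants = (rng.random((S, config.n_plants)) < base_p[None, :]).astype(np.uint8)

    eta = _logit(base_b)[None, :] + config.coupling * (plants @ truth.strength)
    prob_b = 1.0 / (1.0 + np.exp(-eta))
    butterflies = (rng.random((S, config.n_butterflies)) < prob_b).astype(np.uint8)

    if config.symmetric_coupling and config.coupling > 0:
        eta_p = _logit(base_p)[None, :] + config.coupling * (butterflies @ truth.strength.T)
        prob_p = 1.0 / (1.0 + np.exp(-eta_p))
        plants = (rng.random((S, config.n_plants)) < prob_p).astype(np.uint8)
    return plants, butterflies


def generate_abundance(plant_presence: np.ndarray, butterfly_presence: np.ndarray,
                       config: SyntheticCommunityConfig,
                       ) -> tuple[OccurrenceData, OccurrenceData]:
    """Abundances on the support of the presence matrices.

    Plants: log-normal percent cover truncated to (0, 100]; butterflies:
    counts >= 1 from a shifted negative binomial with the configured
    dispersion.  Zero wherever the species is absent, so binarizing the
    abundances recovers the presence matrices exactly.
    """
    rng = config.rng(3)
    S = config.n_sites
    cover = rng.lognormal(mean=np.log(5.0), sigma=1.0, size=(S, config.n_plants))
    cover = np.minimum(cover, 100.0) * plant_presence
    k = config.abundance_dispersion
    mean_count = 8.0
    counts = 1 + rng.negative_binomial(k, k / (k + mean_count - 1.0),
                                       size=(S, config.n_butterflies))
    counts = counts * butterfly_presence
    plants = OccurrenceData(sites=_ids("S", S), species=_ids("P", config.n_plants),
                            guild=PLANT, abundance=cover)
    butterflies = OccurrenceData(sites=_ids("S", S), species=_ids("B", config.n_butterflies),
                                 guild=BUTTERFLY, abundance=counts.astype(float))
    return plants, butterflies


def generate_flowers(plants: OccurrenceData, config: SyntheticCommunityConfig,
                     ) -> OccurrenceData:
    """Flower availability: cover x species flowering rate x log-normal noise,
    with phenological dropout zeroing a present plant's flowers entirely."""
    rng = config.rng(4)
    rate = rng.lognormal(mean=np.log(10.0), sigma=0.5, size=plants.n_species)
    noise = rng.lognormal(mean=0.0, sigma=config.flower_noise, size=plants.abundance.shape)
    keep = rng.random(plants.abundance.shape) >= config.flower_dropout
    units = plants.abundance * rate[None, :] * noise * keep
    return OccurrenceData(sites=list(plants.sites), species=list(plants.species),
                          guild=FLOWER, abundance=units)


def generate_visits(truth: InteractionMatrix, plant_presence: np.ndarray,
                    butterfly_presence: np.ndarray,
                    config: SyntheticCommunityConfig) -> pd.DataFrame:
    """Flower-visitation counts per pair, pooled over sites.

    Poisson with mean ``visit_rate * strength * (number of co-occupied
    sites)``; non-links therefore never record a visit.  Long format
    (plant, butterfly, visits).
    """
    rng = config.rng(5)
    co = plant_presence.T.astype(np.int64) @ butterfly_presence.astype(np.int64)
    mean = config.visit_rate * truth.strength * co
    visits = rng.poisson(mean)
    pl, bu = np.meshgrid(np.arange(truth.strength.shape[0]),
                         np.arange(truth.strength.shape[1]), indexing="ij")
    return pd.DataFrame({
        "plant": np.asarray(truth.plants)[pl.ravel()],
        "butterfly": np.asarray(truth.butterflies)[bu.ravel()],
        "visits": visits.ravel(),
    })


@dataclass
class SyntheticCommunity:
    """One fully generated community and its ground truth."""

    config: SyntheticCommunityConfig
    truth: InteractionMatrix
    plants: OccurrenceData
    butterflies: OccurrenceData
    flowers: OccurrenceData
    visits: pd.DataFrame = field(repr=False)


def generate_community(config: SyntheticCommunityConfig) -> SyntheticCommunity:
    """Run the whole generator pipeline for one seed."""
    truth = generate_truth(config)
    plant_presence, butterfly_presence = generate_occupancy(config, truth)
    plants, butterflies = generate_abundance(plant_presence, butterfly_presence, config)
    flowers = generate_flowers(plants, config)
    visits = generate_visits(truth, plant_presence, butterfly_presence, config)
    return SyntheticCommunity(config=config, truth=truth, plants=plants,
                              butterflies=butterflies, flowers=flowers, visits=visits)
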