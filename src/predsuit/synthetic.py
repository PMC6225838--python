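"""Synthetic feeding-link, trait and monitoring-style abundance data.

The generator emulates the shape of a multi-decadal zoobenthos
monitoring design — 16 stations split evenly into exposed and
sheltered coastal zones, each sampled in 1973, 1989, 2000 and 2013 —
together with a literature-style feeding-link table for ~11
benthivorous fish over a prey pool with multi-hot categorical traits.

Prey abundances are lognormal (right-skewed, as benthic grab counts
are); a configurable temporal drift tilts abundances of species
bearing chosen trait categories by ``exp(rate * year_index)``, moving
community trait frequencies smoothly between years without resampling
species identities.  Feeding links arise from latent predator
affinities over trait categories through a logistic match rule, so
link probability rises with predator-prey trait match.

All randomness flows from one seed through independent per-component
streams: changing the assemblage design never perturbs the generated
traits or links.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .types import (
    EXPOSED,
    SHELTERED,
    AssemblageKey,
    AssemblageSet,
    PredatorPreyMatrix,
    PreyTraitMatrix,
    TraitScheme,
    ValidationError,
    default_scheme,
)

__all__ = [
    "SyntheticConfig",
    "Bundle",
    "generate_trait_matrix",
    "generate_pp_links",
    "generate_assemblages",
    "make_monitoring_bundle",
    "variety_increasing_drift",
]

#: assignment weight decay across a one-hot trait's categories; later
#: categories are progressively rarer, as trait categories are in the field
_CATEGORY_DECAY = 0.6


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and distributional knobs; the seed fixes everything."""

    n_predators: int = 11
    n_prey: int = 60
    scheme: TraitScheme = field(default_factory=default_scheme)
    n_sites: int = 16
    years: tuple[int, ...] = (1973, 1989, 2000, 2013)
    exposed_fraction: float = 0.5
    lognormal_mu: float = 1.0
    lognormal_sigma: float = 1.0
    #: category label -> per-year-step exponential tilt rate of the
    #: abundances of species expressing that category
    drift: Mapping[str, float] = field(default_factory=dict)
    affinity_sharpness: float = 4.0
    #: traits whose categories are sampled independently (>=1 enforced)
    multi_hot_traits: tuple[str, ...] = ("Movement",)
    #: single-category traits sampled as one Bernoulli flag
    bernoulli_traits: tuple[str, ...] = ("Protruding",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_predators < 1 or self.n_prey < 2 or self.n_sites < 1:
            raise ValidationError("need >=1 predator, >=2 prey, >=1 site")
        if not self.years:
            raise ValidationError("need at least one sampling year")
        if not 0 <= self.exposed_fraction <= 1:
            raise ValidationError("exposed_fraction must lie in [0, 1]")
        known = set(self.scheme.category_index)
        unknown = sorted(set(self.drift) - known)
        if unknown:
            raise ValidationError(f"drift targets unknown categories: {unknown}")
        rates = np.array(list(self.drift.values()), dtype=float)
        if rates.size and (~np.isfinite(rates) | (np.abs(rates) > 20)).any():
            raise ValidationError(
                "drift rates must be finite and moderate (|rate| <= 20); "
                "larger tilts degenerate assemblages to single categories"
            )
        for t in (*self.multi_hot_traits, *self.bernoulli_traits):
            if t in self.scheme.traits and t in self.multi_hot_traits and t in self.bernoulli_traits:
                raise ValidationError(f"trait {t!r} cannot be both multi-hot and Bernoulli")

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            name: np.random.default_rng(child)
            for name, child in zip(("traits", "links", "abundance"), children)
        }


def generate_trait_matrix(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> PreyTraitMatrix:
    """Draw binary trait rows for the prey pool.

    One-hot traits get exactly one category per species, drawn with
    geometrically decaying weights so later categories are rarer;
    multi-hot traits draw each category independently (at least one
    enforced); Bernoulli traits are a single coin flip.
    """
    rng = rng or config.streams()["traits"]
    scheme = config.scheme
    prey = tuple(f"prey_{j:03d}" for j in range(1, config.n_prey + 1))
    values = np.zeros((config.n_prey, scheme.n_categories), dtype=np.int8)
    col = {c: i for i, c in enumerate(scheme.category_index)}
    for trait in scheme.traits:
        cats = scheme.categories_by_trait[trait]
        idx = [col[c] for c in cats]
        if trait in config.bernoulli_traits or len(cats) == 1:
            values[:, idx[0]] = rng.random(config.n_prey) < 0.5
        elif trait in config.multi_hot_traits:
            draws = rng.random((config.n_prey, len(cats))) < 0.5
            empty = ~draws.any(axis=1)
            draws[empty, rng.integers(0, len(cats), size=int(empty.sum()))] = True
            values[:, idx] = draws
        else:
            w = _CATEGORY_DECAY ** np.arange(len(cats))
            choice = rng.choice(len(cats), size=config.n_prey, p=w / w.sum())
            values[np.arange(config.n_prey), np.array(idx)[choice]] = 1
    # a scheme of only Bernoulli traits can leave a species blank
    blank = values.sum(axis=1) == 0
    if blank.any():
        values[blank, rng.integers(0, scheme.n_categories, size=int(blank.sum()))] = 1
    return PreyTraitMatrix(prey, scheme, values)


def _draw_affinities(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    return rng.normal(size=(config.n_predators, config.scheme.n_categories))


def generate_pp_links(
    tm: PreyTraitMatrix,
    config: SyntheticConfig,
    affinities: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> PredatorPreyMatrix:
    """Draw feeding links from latent predator-category affinities.

    The link probability for predator i and prey j is
    ``expit(sharpness * mean affinity of i over j's categories)``:
    zero sharpness gives coin-flip links, large sharpness a
    deterministic match rule.  Every predator is guaranteed at least
    one prey (its best-matching prey is linked if the draw left none).
    """
    rng = rng or config.streams()["links"]
    if affinities is None:
        affinities = _draw_affinities(config, rng)
    affinities = np.asarray(affinities, dtype=float)
    if affinities.shape != (config.n_predators, tm.scheme.n_categories):
        raise ValidationError("affinity matrix shape mismatch")
    predators = tuple(f"pred_{i:02d}" for i in range(1, config.n_predators + 1))
    n_cats = tm.values.sum(axis=1).astype(float)  # >= 1 by construction
    score = (affinities @ tm.values.T) / n_cats[None, :]
    prob = expit(config.affinity_sharpness * score)
    links = (rng.random(prob.shape) < prob).astype(np.int8)
    empty = links.sum(axis=1) == 0
    if empty.any():
        links[empty, prob[empty].argmax(axis=1)] = 1
    return PredatorPreyMatrix(predators, tm.prey, links)


def generate_assemblages(
    tm: PreyTraitMatrix,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> AssemblageSet:
    """Draw lognormal abundances per (site, year), with trait drift.

    Stations are split into exposed and sheltered blocks; abundances
    are independent lognormal draws per site-year.  Species expressing
    a drift-target category are tilted by ``exp(rate * (yi - mid))``
    where ``yi`` indexes the year sequence and ``mid`` is its midpoint:
    the study midpoint is the neutral community, early years suppress
    the target's bearers and late years favour them, so the community
    frequency of the category rises monotonically in expectation
    without the late-year assemblages collapsing onto a few dominants.
    """
    rng = rng or config.streams()["abundance"]
    n_exposed = round(config.n_sites * config.exposed_fraction)
    keys = []
    rows = []
    tilt_per_step = np.zeros(len(tm.prey))
    for cat, rate in config.drift.items():
        k = tm.scheme.category_index.index(cat)
        tilt_per_step += rate * tm.values[:, k]
    mid = (len(config.years) - 1) / 2
    for s in range(config.n_sites):
        site = f"{s + 1:02d}"
        exposure = EXPOSED if s < n_exposed else SHELTERED
        for yi, year in enumerate(config.years):
            ab = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, len(tm.prey))
            ab = ab * np.exp(tilt_per_step * (yi - mid))
            keys.append(AssemblageKey(site=site, year=year, exposure=exposure))
            rows.append(ab)
    return AssemblageSet(tuple(keys), tm.prey, np.array(rows))


def variety_increasing_drift(
    scheme: TraitScheme, per_step: float = 0.5
) -> dict[str, float]:
    """A drift that raises trait variety: boost each trait's rarest category.

    Under the generator's decaying assignment weights the last category
    of every multi-category trait is the rarest; tilting abundance
    toward its bearers evens out category frequencies, which raises
    both functional dispersion and the availability of scarce
    categories.
    """
    return {
        tuple(cats)[-1]: per_step
        for cats in scheme.categories_by_trait.values()
        if len(cats) > 1
    }


@dataclass(frozen=True)
class Bundle:
    """A complete synthetic input set plus its generating truth."""

    pp: PredatorPreyMatrix
    tm: PreyTraitMatrix
    assemblages: AssemblageSet
    truth: dict


def make_monitoring_bundle(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> Bundle:
    """Generate a full input set in the monitoring-study shape.

    Defaults mirror the study design: 11 predators, 60 prey, 16 sites
    (8 exposed / 8 sheltered) by 4 years.  The returned truth record
    carries the latent affinities and the drift, for parameter-recovery
    tests.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    streams = config.streams()
    tm = generate_trait_matrix(config, rng=streams["traits"])
    link_rng = streams["links"]
    affinities = _draw_affinities(config, link_rng)
    pp = generate_pp_links(tm, config, affinities=affinities, rng=link_rng)
    ab = generate_assemblages(tm, config, rng=streams["abundance"])
    return Bundle(
        pp=pp,
        tm=tm,
        assemblages=ab,
        truth={
            "affinities": affinities,
            "drift": dict(config.drift),
            "config": config,
        },
    )
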