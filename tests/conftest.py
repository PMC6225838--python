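"""Shared fixtures: schemes, small bundles, and a response simulator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from predsuit import (
    SuitabilityTable,
    SyntheticConfig,
    TraitScheme,
    compute_cwm,
    compute_diet_spectrum,
    compute_rs,
    default_scheme,
    make_monitoring_bundle,
    standardize_cwm,
    transform_rs,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scheme() -> TraitScheme:
    return default_scheme()


@pytest.fixture(scope="session")
def small_scheme() -> TraitScheme:
    """Three traits / six categories; all one-hot under the generator."""
    return TraitScheme(
        traits=("size", "position"),
        categories_by_trait={
            "size": ("size_s", "size_m", "size_l"),
            "position": ("pos_in", "pos_epi", "pos_pel"),
        },
    )


@pytest.fixture(scope="session")
def small_config(small_scheme) -> SyntheticConfig:
    """Scaled-down monitoring design: 8 sites x 4 years, 3 predators."""
    return SyntheticConfig(
        n_predators=3,
        n_prey=20,
        scheme=small_scheme,
        n_sites=8,
        multi_hot_traits=(),
        bernoulli_traits=(),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return make_monitoring_bundle(small_config)


@pytest.fixture(scope="session")
def small_records(small_bundle) -> pd.DataFrame:
    """Tidy transformed-suitability records from the small bundle."""
    ds = compute_diet_spectrum(small_bundle.pp, small_bundle.tm)
    cwm = standardize_cwm(compute_cwm(small_bundle.assemblages, small_bundle.tm))
    return transform_rs(compute_rs(ds, cwm)).to_frame()


def simulate_response(
    design: pd.DataFrame,
    seed: int,
    year_effects: dict[int, float] | None = None,
    sd_site: float = 0.3,
    sd_species: float = 0.3,
    sd_trait: float = 0.3,
    sd_resid: float = 1.0,
) -> SuitabilityTable:
    """Draw a transformed response from the mixed-model family.

    Keeps the design columns (predator, trait, category, site, year,
    exposure) of real pipeline records but replaces the response with
    crossed random intercepts plus fixed year shifts and iid noise —
    the data-generating process the trend model assumes.
    """
    rng = np.random.default_rng(seed)
    df = design.copy()
    effects = year_effects or {}

    def level_effects(col: str, sd: float) -> np.ndarray:
        levels = df[col].unique()
        draw = dict(zip(levels, rng.normal(0, sd, len(levels))))
        return df[col].map(draw).to_numpy()

    y = (
        level_effects("site", sd_site)
        + level_effects("predator", sd_species)
        + level_effects("trait", sd_trait)
        + df["year"].map(lambda v: effects.get(v, 0.0)).to_numpy()
        + rng.normal(0, sd_resid, len(df))
    )
    df["rs_transformed"] = y
    return SuitabilityTable(df)
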