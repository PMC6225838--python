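"""DS-weighted bipartite predator-resource webs and species-level indices.

For each assemblage, the lower trophic level is the standardised CWM
availability of the 24 trait categories and the upper level the
predator fish; the link weight is the predator's diet-spectrum
affinity times the availability, w[i, k] = DS[i, k] * CWM_std[k].

Two species-level indices summarise linkage structure per predator:
the sum of interactions (reported both as ``degree``, the count of
non-zero links, and ``strength``, the summed weights) and proportional
similarity,

    PS_i = 1 - 0.5 * sum_k |p_ik - q_k|,

comparing the predator's proportional resource use p against the
proportional availability q; PS = 1 marks a perfect generalist using
resources exactly as offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .community import CWMTable
from .types import AssemblageKey, DietSpectrum, ValidationError

__all__ = [
    "BipartiteWeb",
    "build_web",
    "build_webs",
    "interaction_sums",
    "proportional_similarity",
    "network_index_table",
    "LINK_TOL",
]

logger = logging.getLogger(__name__)

#: weights at or below this are treated as absent links (guards against
#: floating-point products of exact zeros creating phantom links)
LINK_TOL = 1e-12


@dataclass(frozen=True)
class BipartiteWeb:
    """One assemblage's weighted predator x trait-category web."""

    key: AssemblageKey
    predators: tuple[str, ...]
    categories: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    #: standardised CWM availability of each category in this assemblage
    availability: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if w.shape != (len(self.predators), len(self.categories)):
            raise ValidationError("web weights shape mismatch")
        if (w < 0).any():
            raise ValidationError("web weights must be non-negative")
        object.__setattr__(self, "weights", w)


def build_web(ds: DietSpectrum, cwm: CWMTable, assemblage: AssemblageKey) -> BipartiteWeb:
    """Weight each category's availability by every predator's affinity."""
    if cwm.standardized is None:
        raise ValidationError("CWM table is not standardised; call standardize_cwm first")
    if tuple(ds.scheme.category_index) != tuple(cwm.scheme.category_index):
        raise ValidationError("category axes of DS and CWM tables differ")
    try:
        row = cwm.assemblages.index(assemblage)
    except ValueError:
        raise ValidationError(f"assemblage {assemblage.label!r} not in CWM table") from None
    avail = cwm.standardized[row]
    return BipartiteWeb(
        key=assemblage,
        predators=ds.predators,
        categories=ds.scheme.category_index,
        weights=ds.values * avail[None, :],
        availability=avail,
    )


def build_webs(ds: DietSpectrum, cwm: CWMTable) -> list[BipartiteWeb]:
    return [build_web(ds, cwm, key) for key in cwm.assemblages]


def interaction_sums(web: BipartiteWeb, mode: str = "degree") -> pd.Series:
    """Per-predator sum of interactions.

    ``degree`` counts links with weight above the link tolerance (the
    total number of links to the food resource); ``strength`` sums the
    weights themselves.
    """
    if mode == "degree":
        vals = (web.weights > LINK_TOL).sum(axis=1)
    elif mode == "strength":
        vals = web.weights.sum(axis=1)
    else:
        raise ValueError("mode must be 'degree' or 'strength'")
    return pd.Series(vals, index=list(web.predators), name=mode)


def proportional_similarity(web: BipartiteWeb) -> pd.Series:
    """Czekanowski proportional similarity of use vs availability.

    Undefined (NaN, with a warning) for a predator with zero total use
    in the assemblage; undefined for all when nothing is available.
    """
    avail_total = web.availability.sum()
    use_total = web.weights.sum(axis=1)
    ps = np.full(len(web.predators), np.nan)
    if avail_total > 0:
        q = web.availability / avail_total
        ok = use_total > 0
        p = web.weights[ok] / use_total[ok, None]
        ps[ok] = 1.0 - 0.5 * np.abs(p - q[None, :]).sum(axis=1)
    dead = [pr for pr, t in zip(web.predators, use_total) if t == 0]
    if dead or avail_total == 0:
        logger.warning(
            "proportional similarity undefined in %s for: %s",
            web.key.label,
            dead if avail_total > 0 else "all predators (no availability)",
        )
    return pd.Series(ps, index=list(web.predators), name="proportional_similarity")


def network_index_table(ds: DietSpectrum, cwm: CWMTable) -> pd.DataFrame:
    """Tidy per-(predator, assemblage) index table over all webs."""
    frames = []
    for web in build_webs(ds, cwm):
        frames.append(
            pd.DataFrame(
                {
                    "predator": list(web.predators),
                    "site": web.key.site,
                    "year": web.key.year,
                    "exposure": web.key.exposure,
                    "degree": interaction_sums(web, "degree").to_numpy(),
                    "strength": interaction_sums(web, "strength").to_numpy(),
                    "proportional_similarity": proportional_similarity(web).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
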