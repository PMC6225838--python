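"""The food resource-suitability proxy RS and its modelling transforms.

RS relates what a predator prefers to what the prey community offers:
for predator i, trait category k and assemblage a,

    RS[i, k, a] = DS[i, k] * CWM_std[a, k],

the product of the predator's diet-spectrum affinity and the min-max
standardised community-weighted availability of the category.  RS is a
likelihood-style measure bound between 0 and 1: values near 1 mean a
highly available category the predator strongly favours.

For the trend models the response is log-transformed, log(RS + 0.01),
to normalise residuals, and then z-scored to zero mean and unit
variance over the pooled record set (natural log; z-scoring removes
any base dependence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CWMTable
from .types import DietSpectrum, ValidationError

__all__ = [
    "SuitabilityTable",
    "compute_rs",
    "transform_rs",
    "assemblage_mean_suitability",
    "LOG_OFFSET",
]

LOG_OFFSET = 0.01

#: tidy column order of the records frame
_COLUMNS = ["predator", "trait", "category", "site", "year", "exposure", "rs"]


@dataclass(frozen=True)
class SuitabilityTable:
    """Tidy per-(predator, category, assemblage) suitability records."""

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"suitability records lack columns: {missing}")
        rs = self.records["rs"].to_numpy()
        if (rs < -1e-12).any() or (rs > 1 + 1e-12).any():
            raise ValidationError("rs values must lie in [0, 1]")

    @property
    def has_transform(self) -> bool:
        return "rs_transformed" in self.records.columns

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()


def compute_rs(ds: DietSpectrum, cwm: CWMTable) -> SuitabilityTable:
    """Cross every predator-category affinity with standardised availability.

    Produces one record per (predator, category, assemblage); the trait
    owning each category is carried along because the trend models use
    it as a random factor.
    """
    if cwm.standardized is None:
        raise ValidationError("CWM table is not standardised; call standardize_cwm first")
    if tuple(ds.scheme.category_index) != tuple(cwm.scheme.category_index):
        raise ValidationError("category axes of DS and CWM tables differ")
    n_pred, n_cat = ds.values.shape
    n_asm = len(cwm.assemblages)
    # outer product laid out predator-major, then category, then assemblage
    rs = np.einsum("ik,ak->ika", ds.values, cwm.standardized).ravel()
    cats = list(ds.scheme.category_index)
    traits = [ds.scheme.trait_of(c) for c in cats]
    records = pd.DataFrame(
        {
            "predator": np.repeat(list(ds.predators), n_cat * n_asm),
            "trait": np.tile(np.repeat(traits, n_asm), n_pred),
            "category": np.tile(np.repeat(cats, n_asm), n_pred),
            "site": np.tile([k.site for k in cwm.assemblages], n_pred * n_cat),
            "year": np.tile([k.year for k in cwm.assemblages], n_pred * n_cat),
            "exposure": np.tile([k.exposure for k in cwm.assemblages], n_pred * n_cat),
            "rs": rs,
        }
    )
    return SuitabilityTable(records)


def transform_rs(table: SuitabilityTable) -> SuitabilityTable:
    """Append the model response: z-scored natural log of (rs + 0.01).

    The z-score is taken over the full pooled record set; a table whose
    rs values are all identical has no contrast to model and is
    rejected as degenerate.
    """
    records = table.records.copy()
    t = np.log(records["rs"].to_numpy() + LOG_OFFSET)
    sd = t.std(ddof=1) if len(t) > 1 else 0.0
    if sd <= 1e-12 * max(1.0, float(np.abs(t).max())):
        raise ValidationError("constant rs table: transformed response has zero variance")
    records["rs_transformed"] = (t - t.mean()) / sd
    return SuitabilityTable(records)


def assemblage_mean_suitability(table: SuitabilityTable) -> pd.DataFrame:
    """Mean transformed suitability S per assemblage.

    Averages the standardised response over every (predator, category)
    pair, yielding one S value per (site, year, exposure) — the
    community-level suitability used against functional dispersion.
    """
    if not table.has_transform:
        raise ValidationError("transformed values missing; call transform_rs first")
    out = (
        table.records.groupby(["site", "year", "exposure"], sort=True)["rs_transformed"]
        .mean()
        .reset_index()
        .rename(columns={"rs_transformed": "S"})
    )
    return out
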