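"""Domain containers for trait-based predation-suitability analysis.

The analysis links three tables: binary feeding links between predators
and prey (``PredatorPreyMatrix``), binary trait-category memberships of
the prey pool (``PreyTraitMatrix``, governed by a ``TraitScheme``), and
prey abundances per sampled assemblage (``AssemblageSet``).  Each
container validates its invariants on construction so that downstream
metrics can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "TraitScheme",
    "PredatorPreyMatrix",
    "PreyTraitMatrix",
    "AssemblageKey",
    "AssemblageSet",
    "DietSpectrum",
    "default_scheme",
    "default_predators",
    "EXPOSED",
    "SHELTERED",
]

EXPOSED = "exposed"
SHELTERED = "sheltered"


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


class FormatError(ValueError):
    """A file cell or label cannot be interpreted."""


def _array_dataclass_eq(a, b, array_fields: Iterable[str]) -> bool:
    if type(a) is not type(b):
        return NotImplemented
    for f in a.__dataclass_fields__:
        va, vb = getattr(a, f), getattr(b, f)
        if f in array_fields:
            if not np.array_equal(va, vb):
                return False
        elif va != vb:
            return False
    return True


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dupes = [x for x in labels if x in seen or seen.add(x)]  # type: ignore[func-returns-value]
    if dupes:
        raise ValidationError(f"duplicate {what}: {sorted(set(dupes))}")


def _check_binary(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{what} must be binary; found {arr[r, c]!r} at row {r}, column {c}"
        )
    return arr.astype(np.int8)


@dataclass(frozen=True)
class TraitScheme:
    """An ordered catalogue of traits and their categories.

    Category labels are globally unique across traits, so a flat
    predator-by-category or prey-by-category matrix is unambiguous.
    """

    traits: tuple[str, ...]
    categories_by_trait: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.traits) != set(self.categories_by_trait):
            raise ValidationError("traits and categories_by_trait keys differ")
        _check_unique(self.traits, "trait names")
        flat = [c for t in self.traits for c in self.categories_by_trait[t]]
        _check_unique(flat, "category labels")
        if not flat:
            raise ValidationError("scheme has no categories")

    @property
    def category_index(self) -> tuple[str, ...]:
        return tuple(c for t in self.traits for c in self.categories_by_trait[t])

    @property
    def n_categories(self) -> int:
        return len(self.category_index)

    def trait_of(self, category: str) -> str:
        for t in self.traits:
            if category in self.categories_by_trait[t]:
                return t
        raise KeyError(category)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitScheme":
        """Build a scheme from a long table with ``trait`` and ``category`` columns."""
        traits = tuple(dict.fromkeys(df["trait"]))
        by_trait = {
            t: tuple(df.loc[df["trait"] == t, "category"]) for t in traits
        }
        return cls(traits=traits, categories_by_trait=by_trait)


def default_scheme() -> TraitScheme:
    """The packaged zoobenthos trait scheme: 7 traits, 24 categories.

    Covers maximum size, physical protection, fragility, environmental
    position in/on the sediment, energy content, movement mode and
    whether the animal protrudes from the sediment.
    """
    with resources.files("predsuit.data").joinpath("trait_scheme.csv").open() as fh:
        df = pd.read_csv(fh)
    return TraitScheme.from_frame(df)


def default_predators() -> pd.DataFrame:
    """The packaged benthivorous-fish roster (11 species) with family,
    origin and thermal guild."""
    with resources.files("predsuit.data").joinpath("predators.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True, eq=False)
class PredatorPreyMatrix:
    """Binary feeding links; entry (i, j) = 1 iff predator i feeds on prey j."""

    predators: tuple[str, ...]
    prey: tuple[str, ...]
    links: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.predators, "predator identifiers")
        _check_unique(self.prey, "prey identifiers")
        links = _check_binary(np.atleast_2d(self.links), "feeding links")
        if links.shape != (len(self.predators), len(self.prey)):
            raise ValidationError(
                f"links shape {links.shape} does not match "
                f"{len(self.predators)} predators x {len(self.prey)} prey"
            )
        empty = [p for p, row in zip(self.predators, links) if row.sum() == 0]
        if empty:
            raise ValidationError(f"predators with empty diets: {empty}")
        object.__setattr__(self, "links", links)

    def __eq__(self, other) -> bool:
        return _array_dataclass_eq(self, other, ("links",))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.links, index=list(self.predators), columns=list(self.prey))

    def restrict_prey(self, keep: Sequence[str]) -> "PredatorPreyMatrix":
        idx = [self.prey.index(p) for p in keep]
        return PredatorPreyMatrix(self.predators, tuple(keep), self.links[:, idx])


@dataclass(frozen=True, eq=False)
class PreyTraitMatrix:
    """Binary prey-by-category memberships, columns ordered by the scheme."""

    prey: tuple[str, ...]
    scheme: TraitScheme
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.prey, "prey identifiers")
        vals = _check_binary(np.atleast_2d(self.values), "trait values")
        if vals.shape != (len(self.prey), self.scheme.n_categories):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.prey)} prey x {self.scheme.n_categories} categories"
            )
        empty = [p for p, row in zip(self.prey, vals) if row.sum() == 0]
        if empty:
            raise ValidationError(f"prey with no trait categories: {empty}")
        object.__setattr__(self, "values", vals)

    def __eq__(self, other) -> bool:
        return _array_dataclass_eq(self, other, ("values",))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.prey), columns=list(self.scheme.category_index)
        )

    def restrict_prey(self, keep: Sequence[str]) -> "PreyTraitMatrix":
        idx = [self.prey.index(p) for p in keep]
        return PreyTraitMatrix(tuple(keep), self.scheme, self.values[idx])


@dataclass(frozen=True, order=True)
class AssemblageKey:
    """Identity of one sampled prey assemblage: station, year, exposure class."""

    site: str
    year: int
    exposure: str

    def __post_init__(self) -> None:
        if self.exposure not in (EXPOSED, SHELTERED):
            raise ValidationError(
                f"exposure must be {EXPOSED!r} or {SHELTERED!r}, got {self.exposure!r}"
            )

    @property
    def label(self) -> str:
        return f"{'E' if self.exposure == EXPOSED else 'S'}_{self.site}_{self.year}"


@dataclass(frozen=True, eq=False)
class AssemblageSet:
    """Mean prey abundances per assemblage (replicates already averaged).

    Rows with zero total abundance are permitted only when explicitly
    flagged; they are excluded from every downstream metric.
    """

    assemblages: tuple[AssemblageKey, ...]
    prey: tuple[str, ...]
    abundance: np.ndarray = field(repr=False)
    allow_empty: bool = False

    def __post_init__(self) -> None:
        _check_unique([k.label for k in self.assemblages], "assemblage keys")
        _check_unique(self.prey, "prey identifiers")
        ab = np.atleast_2d(np.asarray(self.abundance, dtype=float))
        if ab.shape != (len(self.assemblages), len(self.prey)):
            raise ValidationError(
                f"abundance shape {ab.shape} does not match "
                f"{len(self.assemblages)} assemblages x {len(self.prey)} prey"
            )
        if (ab < 0).any() or not np.isfinite(ab).all():
            raise ValidationError("abundances must be finite and non-negative")
        totals = ab.sum(axis=1)
        if not self.allow_empty and (totals == 0).any():
            empty = [k.label for k, t in zip(self.assemblages, totals) if t == 0]
            raise ValidationError(f"assemblages with zero total abundance: {empty}")
        object.__setattr__(self, "abundance", ab)

    def __eq__(self, other) -> bool:
        return _array_dataclass_eq(self, other, ("abundance",))

    @property
    def nonempty_mask(self) -> np.ndarray:
        return self.abundance.sum(axis=1) > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance,
            index=[k.label for k in self.assemblages],
            columns=list(self.prey),
        )

    def keys_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": [k.site for k in self.assemblages],
                "year": [k.year for k in self.assemblages],
                "exposure": [k.exposure for k in self.assemblages],
            }
        )

    def restrict_prey(self, keep: Sequence[str]) -> "AssemblageSet":
        idx = [self.prey.index(p) for p in keep]
        return AssemblageSet(
            self.assemblages, tuple(keep), self.abundance[:, idx], allow_empty=True
        )


@dataclass(frozen=True, eq=False)
class DietSpectrum:
    """Predator-by-category affinity scores in [0, 1].

    Entry (i, k) is the fraction of predator i's prey species expressing
    category k; 1 means every prey item carries the category.
    """

    predators: tuple[str, ...]
    scheme: TraitScheme
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.predators, "predator identifiers")
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if vals.shape != (len(self.predators), self.scheme.n_categories):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.predators)} predators x {self.scheme.n_categories} categories"
            )
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("diet-spectrum scores must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    def __eq__(self, other) -> bool:
        return _array_dataclass_eq(self, other, ("values",))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.predators), columns=list(self.scheme.category_index)
        )
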