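"""Community-weighted mean traits and functional dispersion of prey assemblages.

The community-weighted mean (CWM) of a binary trait category is the
abundance fraction of the assemblage expressing it; per-category
min-max standardisation over all assemblages rescales CWM to [0, 1] so
that availability is comparable across sites and years.

Functional dispersion (FDis) is the abundance-weighted mean distance
of the species present in an assemblage to their abundance-weighted
centroid in a multivariate trait space.  The default space is a
principal-coordinates embedding of the Gower dissimilarity between
trait rows; for purely binary categories Gower reduces to the simple
mismatch proportion.  FDis is independent of species richness and
invariant to rescaling all abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .types import AssemblageKey, AssemblageSet, PreyTraitMatrix, TraitScheme, ValidationError

__all__ = [
    "CWMTable",
    "FDisTable",
    "compute_cwm",
    "standardize_cwm",
    "gower_dissimilarity",
    "compute_fdis",
    "compute_fdis_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CWMTable:
    """Raw and (optionally) standardised CWM per assemblage and category."""

    assemblages: tuple[AssemblageKey, ...]
    scheme: TraitScheme
    raw: np.ndarray = field(repr=False)
    standardized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        if raw.shape != (len(self.assemblages), self.scheme.n_categories):
            raise ValidationError("raw CWM shape does not match keys x categories")
        if (raw < -1e-12).any() or (raw > 1 + 1e-12).any():
            raise ValidationError("raw CWM of binary categories must lie in [0, 1]")
        object.__setattr__(self, "raw", raw)

    def _frame(self, values: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            values,
            index=[k.label for k in self.assemblages],
            columns=list(self.scheme.category_index),
        )

    def raw_frame(self) -> pd.DataFrame:
        return self._frame(self.raw)

    def standardized_frame(self) -> pd.DataFrame:
        if self.standardized is None:
            raise ValidationError("standardized CWM not computed; call standardize_cwm")
        return self._frame(self.standardized)


@dataclass(frozen=True)
class FDisTable:
    """Functional dispersion per assemblage, with embedding diagnostics."""

    assemblages: tuple[AssemblageKey, ...]
    fdis: np.ndarray
    n_species: np.ndarray
    embedding_info: dict

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "site": [k.site for k in self.assemblages],
                "year": [k.year for k in self.assemblages],
                "exposure": [k.exposure for k in self.assemblages],
                "fdis": self.fdis,
                "n_species": self.n_species,
            }
        )
        return df


def compute_cwm(
    ab: AssemblageSet, tm: PreyTraitMatrix, strict: bool = False
) -> CWMTable:
    """Abundance-weighted mean trait-category expression per assemblage.

    Empty assemblages are dropped with a warning (or rejected under
    ``strict``); the returned table contains only assemblages with
    positive total abundance.
    """
    if ab.prey != tm.prey:
        raise ValidationError("prey lists of abundance and trait tables are not aligned")
    mask = ab.nonempty_mask
    if not mask.all():
        dropped = [k.label for k, m in zip(ab.assemblages, mask) if not m]
        if strict:
            raise ValidationError(f"assemblages with zero total abundance: {dropped}")
        logger.warning("excluding %d empty assemblages: %s", len(dropped), dropped)
    abund = ab.abundance[mask]
    weights = abund / abund.sum(axis=1, keepdims=True)
    raw = weights @ tm.values
    keys = tuple(k for k, m in zip(ab.assemblages, mask) if m)
    return CWMTable(assemblages=keys, scheme=tm.scheme, raw=raw)


def standardize_cwm(cwm: CWMTable, domain: str = "global") -> CWMTable:
    """Min-max standardise each CWM category to [0, 1].

    ``global`` (default) scales over all assemblages jointly, which
    keeps availability comparable across years; ``per_year`` rescales
    within each sampling year.  Constant columns map to 0: a category
    that never varies offers no availability contrast.
    """
    if domain not in ("global", "per_year"):
        raise ValueError("domain must be 'global' or 'per_year'")
    if domain == "global" and len(cwm.assemblages) < 2:
        raise ValidationError("global standardisation needs at least 2 assemblages")
    std = np.zeros_like(cwm.raw)
    if domain == "global":
        groups: Sequence[np.ndarray] = [np.arange(len(cwm.assemblages))]
    else:
        years = np.array([k.year for k in cwm.assemblages])
        groups = [np.flatnonzero(years == y) for y in np.unique(years)]
    for idx in groups:
        block = cwm.raw[idx]
        lo, hi = block.min(axis=0), block.max(axis=0)
        span = hi - lo
        nonconst = span > 0
        std[np.ix_(idx, nonconst)] = (block[:, nonconst] - lo[nonconst]) / span[nonconst]
    return CWMTable(cwm.assemblages, cwm.scheme, cwm.raw, standardized=std)


def gower_dissimilarity(
    tm: PreyTraitMatrix, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Gower dissimilarity over the binary category columns.

    Every category is one symmetric binary variable, so the Gower
    coefficient is the proportion of mismatching columns; values lie in
    [0, 1] with a zero diagonal.
    """
    prey = tuple(subset) if subset is not None else tm.prey
    if not prey:
        raise ValidationError("empty prey subset")
    idx = [tm.prey.index(p) for p in prey]
    rows = tm.values[idx].astype(float)
    if len(prey) == 1:
        d = np.zeros((1, 1))
    else:
        d = squareform(pdist(rows, metric="hamming"))
    return pd.DataFrame(d, index=list(prey), columns=list(prey))


def _pcoa_embedding(d: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, dict]:
    """Classical scaling (PCoA) of a dissimilarity matrix.

    Double-centres -d²/2, retains axes with eigenvalues above ``tol``,
    and scales eigenvectors by sqrt(eigenvalue).  If negative
    eigenvalues exceed the tolerance the embedding is recomputed on
    sqrt-transformed dissimilarities, which for binary-trait Gower is
    exactly Euclidean-embeddable.  The full eigenvalue spectrum
    (including any negatives) is reported in the info dict.
    """
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, 1)), {"eigvals": [0.0], "n_axes": 0, "corrected": False}

    def embed(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centre = np.eye(n) - np.ones((n, n)) / n
        gram = -0.5 * centre @ (mat**2) @ centre
        eigvals, eigvecs = np.linalg.eigh((gram + gram.T) / 2)
        order = np.argsort(eigvals)[::-1]  # descending
        return eigvecs[:, order], eigvals[order]

    vecs, eigvals = embed(d)
    corrected = False
    if eigvals.min() < -tol:
        vecs, eigvals = embed(np.sqrt(d))
        corrected = True
    keep = eigvals > tol
    info = {
        "eigvals": eigvals.tolist(),
        "n_axes": int(keep.sum()),
        "corrected": corrected,
    }
    if not keep.any():  # all points coincide
        return np.zeros((n, 1)), info
    coords = vecs[:, keep] * np.sqrt(eigvals[keep])
    return coords, info


def compute_fdis(
    abundances: Sequence[float],
    tm: PreyTraitMatrix,
    space: str = "pcoa_gower",
) -> tuple[float, dict]:
    """Functional dispersion of one assemblage.

    ``abundances`` is aligned with ``tm.prey``; only species with
    positive abundance enter.  Returns (fdis, embedding_info).  A single
    present species, or identical trait rows, give 0.
    """
    if space not in ("pcoa_gower", "euclidean_raw"):
        raise ValueError("space must be 'pcoa_gower' or 'euclidean_raw'")
    a = np.asarray(abundances, dtype=float)
    if a.shape != (len(tm.prey),):
        raise ValidationError("abundance vector is not aligned with the trait matrix")
    present = a > 0
    if not present.any():
        raise ValidationError("assemblage has no species with positive abundance")
    w = a[present]
    if present.sum() == 1:
        return 0.0, {"n_axes": 0, "corrected": False, "eigvals": []}
    if space == "euclidean_raw":
        coords = tm.values[present].astype(float)
        info = {"n_axes": coords.shape[1], "corrected": False, "eigvals": []}
    else:
        subset = [p for p, m in zip(tm.prey, present) if m]
        d = gower_dissimilarity(tm, subset).to_numpy()
        coords, info = _pcoa_embedding(d)
    centroid = (w[:, None] * coords).sum(axis=0) / w.sum()
    dist = np.linalg.norm(coords - centroid, axis=1)
    return float((w * dist).sum() / w.sum()), info


def compute_fdis_table(
    ab: AssemblageSet, tm: PreyTraitMatrix, space: str = "pcoa_gower"
) -> FDisTable:
    """FDis for every non-empty assemblage of the set."""
    if ab.prey != tm.prey:
        raise ValidationError("prey lists of abundance and trait tables are not aligned")
    mask = ab.nonempty_mask
    keys = tuple(k for k, m in zip(ab.assemblages, mask) if m)
    fdis = np.empty(len(keys))
    nsp = np.empty(len(keys), dtype=int)
    info: dict = {}
    for i, row in enumerate(ab.abundance[mask]):
        fdis[i], info = compute_fdis(row, tm, space=space)
        nsp[i] = int((row > 0).sum())
    return FDisTable(keys, fdis, nsp, {"space": space, "last": info})
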