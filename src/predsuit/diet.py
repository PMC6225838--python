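"""Trait-based diet spectra and predator similarity grouping.

A predator's diet spectrum (DS) translates its binary prey list into
affinities for prey trait categories: the score for category k is the
fraction of the predator's prey species expressing k,

    DS[i, k] = sum_j PP[i, j] * T[j, k] / sum_j PP[i, j],

so 1 means every prey item carries the category and 0 means none does.
The spectrum is frequency-based over prey species presence/absence; it
carries no information on how often individual prey are ingested.

Predators are grouped by agglomerative clustering of their DS rows;
the tree is descriptive (which predators feed alike), not inferential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .types import DietSpectrum, PredatorPreyMatrix, PreyTraitMatrix, ValidationError

__all__ = ["compute_diet_spectrum", "cluster_diet_spectra", "DietSimilarityTree"]


def compute_diet_spectrum(pp: PredatorPreyMatrix, tm: PreyTraitMatrix) -> DietSpectrum:
    """Compute per-predator trait-category affinity scores.

    Requires the prey axes of the two tables to be identical (use
    :func:`predsuit.io.align_prey` first when they are not).
    """
    if pp.prey != tm.prey:
        raise ValidationError(
            "prey lists of the link and trait tables are not aligned"
        )
    diet_sizes = pp.links.sum(axis=1).astype(float)  # >= 1 by construction
    values = (pp.links @ tm.values) / diet_sizes[:, None]
    return DietSpectrum(pp.predators, tm.scheme, values)


@dataclass(frozen=True)
class DietSimilarityTree:
    """Agglomerative grouping of predators by diet-spectrum similarity.

    ``merge_history`` lists n-1 merges as (members_a, members_b, height)
    with cluster members given as sorted tuples of predator labels and
    heights non-decreasing under the supported linkages.
    """

    leaves: tuple[str, ...]
    merge_history: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]
    distance_metric: str
    linkage: str

    def __post_init__(self) -> None:
        if len(self.merge_history) != len(self.leaves) - 1:
            raise ValidationError("a tree over n leaves must record n-1 merges")
        heights = [h for _, _, h in self.merge_history]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        """Serialise as Newick with branch lengths from merge heights.

        A leaf's branch length is the height of the merge that absorbs
        it; an internal node's is the height difference to its parent
        (ultrametric tree, leaves at height 0).
        """
        node: dict[tuple[str, ...], tuple[str, float]] = {
            (lf,): (_escape(lf), 0.0) for lf in self.leaves
        }
        cluster = None
        for a, b, h in self.merge_history:
            (sa, ha), (sb, hb) = node.pop(a), node.pop(b)
            cluster = tuple(sorted(a + b))
            node[cluster] = (f"({sa}:{h - ha:.12g},{sb}:{h - hb:.12g})", h)
        return node[cluster][0] + ";" if cluster else _escape(self.leaves[0]) + ";"


def _escape(label: str) -> str:
    return "'" + label.replace("'", "''") + "'" if set(" ():;,'[]") & set(label) else label


_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


def cluster_diet_spectra(
    ds: DietSpectrum, metric: str = "euclidean", linkage: str = "average"
) -> DietSimilarityTree:
    """Cluster predators agglomeratively on their raw DS row vectors.

    UPGMA (``average``) on Euclidean distances is the default; complete
    linkage and Manhattan distance are offered.  Ties in merge distance
    are broken lexicographically by the smallest member label of the
    candidate pair, so the tree is deterministic.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    if len(ds.predators) < 2:
        raise ValidationError("clustering needs at least 2 predators")

    dist = squareform(pdist(ds.values, metric=_METRICS[metric]))
    # Lance-Williams style agglomeration over label-sorted active clusters.
    clusters: dict[tuple[str, ...], list[int]] = {
        (p,): [i] for i, p in enumerate(ds.predators)
    }
    history: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best: tuple[float, tuple[str, ...], tuple[str, ...]] | None = None
        for ia, ka in enumerate(keys):
            for kb in keys[ia + 1 :]:
                block = dist[np.ix_(clusters[ka], clusters[kb])]
                d = block.mean() if linkage == "average" else block.max()
                if best is None or d < best[0] - 1e-15:
                    best = (d, ka, kb)
        d, ka, kb = best  # type: ignore[misc]
        history.append((ka, kb, float(d)))
        clusters[tuple(sorted(ka + kb))] = clusters.pop(ka) + clusters.pop(kb)
    return DietSimilarityTree(
        leaves=ds.predators,
        merge_history=tuple(history),
        distance_metric=metric,
        linkage=linkage,
    )
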