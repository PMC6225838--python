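"""CWM, min-max standardisation, Gower dissimilarity and FDis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from predsuit import (
    AssemblageKey,
    AssemblageSet,
    CWMTable,
    PreyTraitMatrix,
    TraitScheme,
    ValidationError,
    compute_cwm,
    compute_fdis,
    compute_fdis_table,
    gower_dissimilarity,
    standardize_cwm,
)
from predsuit.community import _pcoa_embedding
from predsuit.types import EXPOSED, SHELTERED


def flat_scheme(n: int) -> TraitScheme:
    return TraitScheme(("t",), {"t": tuple(f"c{k}" for k in range(n))})


def trait_matrix(values: np.ndarray) -> PreyTraitMatrix:
    n, k = values.shape
    return PreyTraitMatrix(tuple(f"j{i}" for i in range(n)), flat_scheme(k), values)


def assemblages(abundance: np.ndarray, prey: tuple[str, ...]) -> AssemblageSet:
    keys = tuple(
        AssemblageKey(f"{i:02d}", 1973, EXPOSED if i % 2 else SHELTERED)
        for i in range(abundance.shape[0])
    )
    return AssemblageSet(keys, prey, abundance, allow_empty=True)


class TestCWM:
    def test_weighted_mean_of_binary_expression(self):
        tm = trait_matrix(np.array([[1, 1], [0, 1]]))
        ab = assemblages(np.array([[3.0, 1.0]]), tm.prey)
        cwm = compute_cwm(ab, tm)
        assert cwm.raw[0, 0] == pytest.approx(0.75)
        assert cwm.raw[0, 1] == pytest.approx(1.0)

    def test_single_species_assemblage_copies_trait_row(self):
        tm = trait_matrix(np.array([[1, 0, 1], [0, 1, 1]]))
        ab = assemblages(np.array([[0.0, 5.0]]), tm.prey)
        cwm = compute_cwm(ab, tm)
        np.testing.assert_array_equal(cwm.raw[0], [0, 1, 1])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_category_loop(self, seed):
        rng = np.random.default_rng(seed)
        traits = rng.integers(0, 2, (6, 8))
        traits[:, 0] = 1
        tm = trait_matrix(traits)
        abund = rng.lognormal(0, 1, (4, 6))
        ab = assemblages(abund, tm.prey)
        cwm = compute_cwm(ab, tm)
        for a in range(4):
            total = abund[a].sum()
            for k in range(8):
                expect = sum(abund[a, j] * traits[j, k] for j in range(6)) / total
                assert cwm.raw[a, k] == pytest.approx(expect, abs=1e-12)

    def test_one_hot_trait_categories_sum_to_one(self):
        """Categories that partition the species pool conserve total weight."""
        rng = np.random.default_rng(9)
        onehot = np.eye(3, dtype=int)[rng.integers(0, 3, 10)]
        tm = trait_matrix(onehot)
        ab = assemblages(rng.lognormal(0, 1, (5, 10)), tm.prey)
        cwm = compute_cwm(ab, tm)
        np.testing.assert_allclose(cwm.raw.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_assemblage_excluded(self):
        tm = trait_matrix(np.array([[1, 0], [0, 1]]))
        ab = assemblages(np.array([[1.0, 1.0], [0.0, 0.0]]), tm.prey)
        cwm = compute_cwm(ab, tm)
        assert len(cwm.assemblages) == 1
        with pytest.raises(ValidationError, match="zero total"):
            compute_cwm(ab, tm, strict=True)


class TestStandardize:
    def test_min_max_column(self):
        keys = 3
        table = CWMTable(
            tuple(AssemblageKey(f"{i}", 1973, SHELTERED) for i in range(keys)),
            flat_scheme(1),
            np.array([[0.2], [0.4], [0.6]]),
        )
        out = standardize_cwm(table)
        np.testing.assert_allclose(out.standardized[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        table = CWMTable(
            tuple(AssemblageKey(f"{i}", 1973, SHELTERED) for i in range(2)),
            flat_scheme(1),
            np.array([[0.3], [0.3]]),
        )
        out = standardize_cwm(table)
        np.testing.assert_array_equal(out.standardized, [[0.0], [0.0]])

    def test_columns_attain_bounds(self):
        rng = np.random.default_rng(1)
        raw = rng.random((10, 4))
        table = CWMTable(
            tuple(AssemblageKey(f"{i}", 1973, SHELTERED) for i in range(10)),
            flat_scheme(4),
            raw,
        )
        std = standardize_cwm(table).standardized
        np.testing.assert_allclose(std.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(std.max(axis=0), 1.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        raw = rng.random((8, 3))
        keys = tuple(AssemblageKey(f"{i}", 1973, SHELTERED) for i in range(8))
        once = standardize_cwm(CWMTable(keys, flat_scheme(3), raw)).standardized
        twice = standardize_cwm(CWMTable(keys, flat_scheme(3), once)).standardized
        np.testing.assert_allclose(twice, once, atol=1e-14)

    def test_per_year_domain_scales_within_years(self):
        keys = tuple(
            AssemblageKey(f"{i}", year, SHELTERED)
            for year in (1973, 1989)
            for i in range(2)
        )
        raw = np.array([[0.1], [0.2], [0.5], [0.9]])
        out = standardize_cwm(CWMTable(keys, flat_scheme(1), raw), domain="per_year")
        np.testing.assert_allclose(out.standardized[:, 0], [0, 1, 0, 1])


class TestGower:
    def test_identical_rows_have_zero_dissimilarity(self):
        tm = trait_matrix(np.tile([1, 0, 1, 0], (3, 1)))
        d = gower_dissimilarity(tm).to_numpy()
        np.testing.assert_array_equal(d, np.zeros((3, 3)))

    def test_mismatch_proportion(self):
        rows = np.zeros((2, 24), dtype=int)
        rows[0, :6] = 1  # differ in 6 of 24 columns
        rows[:, 23] = 1
        tm = trait_matrix(rows)
        d = gower_dissimilarity(tm).to_numpy()
        assert d[0, 1] == pytest.approx(6 / 24)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_column_mismatch_count(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, (5, 24))
        rows[:, 0] = 1
        tm = trait_matrix(rows)
        d = gower_dissimilarity(tm).to_numpy()
        for a in range(5):
            for b in range(5):
                mismatches = int((rows[a] != rows[b]).sum())
                assert d[a, b] == pytest.approx(mismatches / 24, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_bounds_symmetry_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, (4, 6))
        rows[:, 0] = 1
        d = gower_dissimilarity(trait_matrix(rows)).to_numpy()
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_array_equal(d, d.T)
        np.testing.assert_array_equal(np.diag(d), 0)

    def test_empty_subset_rejected(self):
        tm = trait_matrix(np.array([[1, 0]]))
        with pytest.raises(ValidationError, match="empty"):
            gower_dissimilarity(tm, subset=())


class TestFDis:
    def test_monoculture_is_zero(self):
        tm = trait_matrix(np.array([[1, 0], [0, 1]]))
        fdis, _ = compute_fdis([5.0, 0.0], tm)
        assert fdis == 0.0

    def test_two_equal_species_give_half_distance(self):
        rows = np.zeros((2, 24), dtype=int)
        rows[0, :6] = 1
        rows[:, 23] = 1
        tm = trait_matrix(rows)
        d = gower_dissimilarity(tm).to_numpy()[0, 1]
        fdis, _ = compute_fdis([1.0, 1.0], tm)
        assert fdis == pytest.approx(d / 2, abs=1e-12)

    def test_unequal_weights_two_point_case(self):
        """Points at distance 1 with abundances 3:1 -> FDis = 0.375."""
        rows = np.array([[1] * 24, [0] * 23 + [1]])
        rows[1, 23] = 1
        rows[0, 23] = 0  # rows differ in every column -> Gower distance 1
        tm = trait_matrix(rows)
        fdis, _ = compute_fdis([3.0, 1.0], tm)
        assert fdis == pytest.approx(0.375, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        rows = rng.integers(0, 2, (8, 24))
        rows[:, 0] = 1
        tm = trait_matrix(rows)
        a = rng.lognormal(0, 1, 8)
        base, _ = compute_fdis(a, tm)
        for c in (1e-6, 3.7, 1e6):
            scaled, _ = compute_fdis(c * a, tm)
            assert abs(scaled - base) < 1e-12

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_embedding_recomputation(self, seed):
        """FDis agrees with a from-scratch PCoA + weighted-centroid loop."""
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, (8, 24))
        rows[:, 0] = 1
        tm = trait_matrix(rows)
        a = rng.lognormal(0, 1, 8)
        fdis, info = compute_fdis(a, tm)

        # independent route: hamming distances, eigendecomposition via svd
        d = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                d[i, j] = (rows[i] != rows[j]).mean()
        if info["corrected"]:
            d = np.sqrt(d)
        j8 = np.eye(8) - np.ones((8, 8)) / 8
        gram = -0.5 * j8 @ (d**2) @ j8
        vals, vecs = np.linalg.eigh(gram)
        coords = vecs[:, vals > 1e-8] * np.sqrt(vals[vals > 1e-8])
        centroid = (a[:, None] * coords).sum(axis=0) / a.sum()
        expect = (a * np.linalg.norm(coords - centroid, axis=1)).sum() / a.sum()
        assert fdis == pytest.approx(expect, abs=1e-10)

    def test_separation_monotonicity_euclidean(self):
        """Moving one species away from the rest cannot decrease FDis."""
        base_rows = np.zeros((4, 24), dtype=int)
        base_rows[:, 0] = 1
        a = np.array([1.0, 2.0, 1.0, 1.0])
        prev = -1.0
        for extra in range(0, 12):
            rows = base_rows.copy()
            rows[3, 1 : 1 + extra] = 1
            fdis, _ = compute_fdis(a, trait_matrix(rows), space="euclidean_raw")
            assert fdis >= prev - 1e-12
            prev = fdis

    def test_sqrt_correction_triggers_on_non_euclidean_gower(self):
        # 2-column binary rows 00/11/01/10: Gower is not Euclidean-embeddable
        rows = np.array([[0, 1], [1, 0], [0, 0], [1, 1]])
        rows = np.hstack([rows, np.ones((4, 1), dtype=int)])
        fdis, info = compute_fdis([1.0, 1, 1, 1], trait_matrix(rows))
        assert info["corrected"]
        assert np.isfinite(fdis) and fdis > 0

    def test_agrees_with_skbio_pcoa_when_euclidean(self):
        """Our classical scaling matches skbio's on an embeddable matrix."""
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(8)
        pts = rng.random((6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, info = _pcoa_embedding(d)
        sk = pcoa(d, method="eigh", warn_neg_eigval=False)
        k = info["n_axes"]
        np.testing.assert_allclose(
            np.abs(coords), np.abs(sk.samples.to_numpy()[:, :k]), atol=1e-8
        )

    def test_table_excludes_empty_assemblages(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, (5, 6))
        rows[:, 0] = 1
        tm = trait_matrix(rows)
        abund = rng.lognormal(0, 1, (3, 5))
        abund[1] = 0.0
        ab = assemblages(abund, tm.prey)
        table = compute_fdis_table(ab, tm)
        assert len(table.assemblages) == 2
        assert (table.n_species > 0).all()
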