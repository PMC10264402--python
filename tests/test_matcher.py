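"""Correlation matchers: profile building, the scaled transform, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stmatch import (
    BootstrapConfig,
    ReferenceProfiles,
    cluster_profiles,
    correlate_cell,
    match_bootstrap,
    match_correlation,
    scaled_probability,
)

from conftest import make_cells


def profiles_from(rows, types=None, genes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    types = types or [f"T{i}" for i in range(len(rows))]
    genes = genes or [f"g{j}" for j in range(rows.shape[1])]
    return ReferenceProfiles(
        types=types, profiles=pd.DataFrame(rows, index=types, columns=genes)
    )


class TestClusterProfiles:
    def test_median_of_two_cells(self):
        counts = pd.DataFrame([[1, 3], [3, 5]], columns=["g0", "g1"])
        ref = cluster_profiles(counts, ["A", "A"], statistic="median")
        np.testing.assert_allclose(ref.profiles.loc["A"], [2, 4])

    def test_singleton_type_equals_the_cell(self):
        counts = pd.DataFrame([[7, 1, 4]], columns=list("abc"))
        ref = cluster_profiles(counts, ["A"])
        np.testing.assert_allclose(ref.profiles.loc["A"], [7, 1, 4])

    def test_mean_vs_median_on_skewed_counts(self):
        counts = pd.DataFrame([[0], [0], [9]], columns=["g"])
        labels = ["A"] * 3
        assert cluster_profiles(counts, labels, "mean").profiles.loc["A", "g"] == 3
        assert cluster_profiles(counts, labels, "median").profiles.loc["A", "g"] == 0

    def test_empty_type_is_an_error(self):
        counts = pd.DataFrame([[1, 2]], columns=["g0", "g1"])
        with pytest.raises(ValueError, match="B"):
            cluster_profiles(counts, ["A"], type_order=["A", "B"])


class TestCorrelateCell:
    def test_identical_vector_gives_unit_correlation(self):
        ref = profiles_from([[1, 2, 3], [3, 1, 2]])
        r = correlate_cell(np.array([1.0, 2, 3]), ref)
        assert r[0] == pytest.approx(1.0)

    def test_reversed_vector_gives_minus_one(self):
        ref = profiles_from([[1, 2, 3]])
        r = correlate_cell(np.array([3.0, 2, 1]), ref)
        assert r[0] == pytest.approx(-1.0)

    def test_constant_cell_vector_scores_zero_not_nan(self):
        ref = profiles_from([[1, 2, 3]])
        r = correlate_cell(np.array([5.0, 5, 5]), ref)
        np.testing.assert_array_equal(r, [0.0])

    def test_too_few_genes_rejected(self):
        ref = profiles_from([[1.0]])
        with pytest.raises(ValueError):
            correlate_cell(np.array([1.0]), ref)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.floats(0.1, 10.0), st.floats(-5.0, 5.0), st.integers(0, 2**31 - 1)
    )
    def test_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        cell = rng.random(6)
        ref = profiles_from(rng.random((2, 6)))
        base = correlate_cell(cell, ref)
        rescaled = correlate_cell(scale * cell + shift, ref)
        np.testing.assert_allclose(rescaled, base, atol=1e-8)


class TestScaledProbability:
    @pytest.mark.parametrize(
        "y,expected",
        [
            ([0.8, 0.4, 0.2], [1.0, 0.0, 0.0]),  # s = (0.16, 0, 0)
            ([0.6, 0.6], [0.5, 0.5]),  # s = (0.09, 0.09)
            ([-0.2, -0.5], [0.0, 0.0]),  # no positive mass: unassigned row
        ],
    )
    def test_hand_worked_cases(self, y, expected):
        np.testing.assert_allclose(scaled_probability(np.array(y)), expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            scaled_probability(np.array([]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 20))
    def test_argmax_preserved_and_rows_normalized(self, seed, n):
        y = np.random.default_rng(seed).uniform(-1, 1, n)
        p = scaled_probability(y)
        if p.sum() > 0:
            assert p.argmax() == y.argmax()
            assert abs(p.sum() - 1.0) <= 1e-12
        else:
            assert y.max() <= 0


class TestMatchCorrelation:
    def test_cell_equal_to_profile_is_one_hot(self):
        ref = profiles_from([[5, 1, 0, 2], [0, 4, 4, 0], [1, 1, 5, 3]])
        cells = make_cells([[5, 1, 0, 2]])
        cm = match_correlation(cells, ref, normalize=False)
        np.testing.assert_allclose(cm.scores[0], [1, 0, 0], atol=1e-12)

    def test_noisy_cell_keeps_argmax(self):
        rng = np.random.default_rng(0)
        ref_rows = rng.uniform(0, 10, (4, 30))
        cells = make_cells(np.clip(ref_rows[2] + rng.normal(0, 0.3, 30), 0, None))
        cm = match_correlation(cells, profiles_from(ref_rows), normalize=False)
        assert cm.scores[0].argmax() == 2

    def test_duplicate_profiles_split_mass_evenly(self):
        row = np.array([3.0, 1, 0, 2, 5])
        ref = profiles_from([row, row, [0, 5, 5, 0, 0]])
        cm = match_correlation(make_cells(row), ref, normalize=False)
        np.testing.assert_allclose(cm.scores[0], [0.5, 0.5, 0.0], atol=1e-12)

    def test_rows_sum_to_one_or_zero(self, tissue, reference, spec):
        _, cells, _ = tissue
        ref = cluster_profiles(*reference, type_order=spec.subclasses)
        cm = match_correlation(cells.subset(cells.cells[:200]), ref)
        sums = cm.scores.sum(axis=1)
        assert np.all((np.abs(sums - 1) <= 1e-12) | (sums == 0))


class TestMatchBootstrap:
    def test_single_round_full_panel_is_one_hot_argmax(self):
        rng = np.random.default_rng(1)
        ref_rows = rng.uniform(0, 10, (3, 12))
        cells = make_cells(ref_rows[1])
        cfg = BootstrapConfig(rounds=1, gene_fraction=1.0, seed=0)
        cm = match_bootstrap(cells, profiles_from(ref_rows), cfg, normalize=False)
        np.testing.assert_array_equal(cm.scores[0], [0, 1, 0])

    def test_same_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(2)
        ref_rows = rng.uniform(0, 10, (3, 20))
        cells = make_cells(rng.uniform(0, 10, (5, 20)))
        cfg = BootstrapConfig(rounds=25, gene_fraction=0.6, seed=9)
        a = match_bootstrap(cells, profiles_from(ref_rows), cfg)
        b = match_bootstrap(cells, profiles_from(ref_rows), cfg)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_separated_profiles_give_confident_votes(self):
        # orthogonal marker blocks: every subsample still separates types
        ref_rows = np.kron(np.eye(3), np.full(8, 10.0)) + 0.1
        cells = make_cells(ref_rows[0])
        cfg = BootstrapConfig(rounds=100, gene_fraction=0.8, seed=4)
        cm = match_bootstrap(cells, profiles_from(ref_rows), cfg, normalize=False)
        assert cm.scores[0, 0] >= 0.99

    def test_duplicated_profiles_split_votes(self):
        rng = np.random.default_rng(5)
        row = rng.uniform(0, 10, 15)
        other = rng.uniform(0, 10, 15)
        ref = profiles_from([row, row, other])
        cells = make_cells(np.clip(row + rng.normal(0, 0.5, 15), 0, None))
        cfg = BootstrapConfig(rounds=200, gene_fraction=0.7, seed=6)
        cm = match_bootstrap(cells, ref, cfg, normalize=False)
        # exact correlation ties per round go to the first type in taxonomy
        # order; noise in the cell keeps the two duplicates exactly tied
        assert cm.scores[0, 0] + cm.scores[0, 1] >= 0.99

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        ref_rows = rng.uniform(0, 10, (4, 10))
        cells = make_cells(rng.uniform(0, 10, (6, 10)))
        cm = match_bootstrap(
            cells, profiles_from(ref_rows), BootstrapConfig(rounds=17, seed=3)
        )
        np.testing.assert_allclose(cm.scores.sum(axis=1), 1.0, atol=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BootstrapConfig(rounds=0)
        with pytest.raises(ValueError):
            BootstrapConfig(gene_fraction=0.0)
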