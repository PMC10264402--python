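"""Consensus combiners: geometric-median and negative-weighting strategies."""

import numpy as np
import pytest

from stmatch import (
    ConfidenceMatrix,
    MedianSolverConfig,
    UNASSIGNED,
    deterministic_assignment,
    gmcs_combine,
    nwcs_combine,
    weiszfeld_median,
)
from stmatch.synthetic import NoiseModel, accuracy, generate_confidences


def cm_from(rows, types=None, name="m", bounded=True):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    types = types or [f"T{i}" for i in range(rows.shape[1])]
    return ConfidenceMatrix(
        cells=[f"c{i}" for i in range(len(rows))], types=types, scores=rows,
        method_name=name, bounded=bounded,
    )


def simplex_grid(n, step):
    """Dense grid over the probability simplex in R^n (n = 2 or 3)."""
    ts = np.arange(0.0, 1.0 + step / 2, step)
    if n == 2:
        return np.column_stack([ts, 1 - ts])
    a, b = np.meshgrid(ts, ts, indexing="ij")
    keep = a + b <= 1 + 1e-12
    return np.column_stack([a[keep], b[keep], 1 - a[keep] - b[keep]])


def grid_minimize(points, step=1e-3):
    """Brute-force geometric median over the simplex grid."""
    grid = simplex_grid(points.shape[1], step)
    objective = np.zeros(len(grid))
    for p in points:
        objective += np.linalg.norm(grid - p, axis=1)
    return grid[objective.argmin()], objective.min()


def total_distance(p, points):
    return float(np.linalg.norm(points - p, axis=1).sum())


class TestWeiszfeldMedian:
    def test_identical_points_returned_exactly(self):
        pts = np.tile([0.2, 0.5, 0.3], (5, 1))
        np.testing.assert_array_equal(weiszfeld_median(pts), pts[0])

    def test_two_points_resolve_to_midpoint(self):
        pts = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(weiszfeld_median(pts), [0.5, 0.5])

    def test_collinear_points_return_the_middle_one(self):
        pts = np.array([[1.0, 0.0], [0.6, 0.4], [0.0, 1.0]])
        med = weiszfeld_median(pts)
        grid_point, _ = grid_minimize(pts)
        np.testing.assert_allclose(grid_point, [0.6, 0.4], atol=1e-9)
        np.testing.assert_allclose(med, [0.6, 0.4], atol=1e-6)

    def test_majority_coincident_point_wins(self):
        # > m/2 points at v pins the median at v (Vardi–Zhang certificate)
        pts = np.array(
            [[0.1, 0.9], [0.1, 0.9], [0.1, 0.9], [0.9, 0.1], [0.5, 0.5]]
        )
        np.testing.assert_allclose(weiszfeld_median(pts), [0.1, 0.9], atol=1e-9)

    def test_matches_simplex_grid_oracle(self):
        rng = np.random.default_rng(13)
        for i in range(25):
            n = 2 if i % 2 == 0 else 3
            m = int(rng.integers(3, 7))
            if n == 2 and m % 2 == 0:
                m += 1  # unique 1-D median needs odd multiplicity
            pts = rng.dirichlet(np.ones(n), size=m)
            med = weiszfeld_median(pts)
            grid_point, grid_obj = grid_minimize(pts, step=1e-3)
            assert total_distance(med, pts) <= grid_obj + 1e-3
            np.testing.assert_allclose(med, grid_point, atol=2e-3)

    def test_objective_no_worse_than_mean_or_any_vertex(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 4))
        med = weiszfeld_median(pts)
        best_input = min(total_distance(p, pts) for p in pts)
        assert total_distance(med, pts) <= total_distance(pts.mean(0), pts) + 1e-9
        assert total_distance(med, pts) <= best_input + 1e-9

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            weiszfeld_median(np.array([[np.nan, 1.0]]))


class TestGMCS:
    def test_equal_inputs_pass_through(self):
        rows = np.array([[0.2, 0.5, 0.3], [1.0, 0.0, 0.0]])
        out = gmcs_combine([cm_from(rows, name=f"m{i}") for i in range(3)])
        np.testing.assert_allclose(out.scores, rows, atol=1e-9)

    def test_method_order_is_irrelevant(self):
        rng = np.random.default_rng(4)
        mats = [cm_from(rng.dirichlet(np.ones(4), size=6), name=f"m{i}") for i in range(4)]
        fwd = gmcs_combine(mats)
        rev = gmcs_combine(mats[::-1])
        np.testing.assert_allclose(fwd.scores, rev.scores, atol=1e-9)

    def test_collinear_rows_combine_to_middle_row(self):
        mats = [
            cm_from([[1.0, 0.0]]),
            cm_from([[0.6, 0.4]]),
            cm_from([[0.0, 1.0]]),
        ]
        out = gmcs_combine(mats)
        np.testing.assert_allclose(out.scores[0], [0.6, 0.4], atol=1e-6)

    def test_output_rows_stay_on_simplex(self):
        rng = np.random.default_rng(5)
        mats = [cm_from(rng.dirichlet(np.ones(5), size=30), name=f"m{i}") for i in range(5)]
        out = gmcs_combine(mats)
        assert (out.scores >= 0).all()
        np.testing.assert_allclose(out.scores.sum(axis=1), 1.0, atol=1e-6)

    def test_renormalization_rescales_incomparable_rows(self):
        raw = cm_from([[0.2, 0.1, 0.1]])  # sums to 0.4
        out = gmcs_combine([raw])
        np.testing.assert_allclose(out.scores[0], [0.5, 0.25, 0.25])

    def test_shape_mismatch_names_offender(self):
        a = cm_from([[0.5, 0.5]], name="a")
        b = cm_from([[0.5, 0.3, 0.2]], name="b")
        with pytest.raises(ValueError, match="'b'"):
            gmcs_combine([a, b])


class TestNWCS:
    def test_agreeing_methods_sum_top_scores(self):
        # both methods put type A on top: A keeps 0.9 + 0.8, rest get -2
        m1 = cm_from([[0.9, 0.05, 0.05]])
        m2 = cm_from([[0.8, 0.15, 0.05]])
        out = nwcs_combine([m1, m2])
        np.testing.assert_allclose(out.scores[0], [1.7, -2.0, -2.0])

    def test_disagreeing_methods_keep_both_tops(self):
        m1 = cm_from([[0.9, 0.05, 0.05]])  # top A at 0.9
        m2 = cm_from([[0.03, 0.95, 0.02]])  # top B at 0.95
        out = nwcs_combine([m1, m2])
        np.testing.assert_allclose(out.scores[0], [-0.1, -0.05, -2.0])
        labels = deterministic_assignment(out)
        assert labels.labels[0] == "T1"

    def test_single_method_keeps_argmax(self):
        m1 = cm_from([[0.2, 0.7, 0.1]])
        out = nwcs_combine([m1])
        np.testing.assert_allclose(out.scores[0], [-1.0, 0.7, -1.0])
        assert deterministic_assignment(out).labels[0] == "T1"

    def test_tied_top_scores_both_retained_by_default(self):
        m1 = cm_from([[0.5, 0.5, 0.0]])
        out_all = nwcs_combine([m1], tie_policy="all")
        np.testing.assert_allclose(out_all.scores[0], [0.5, 0.5, -1.0])
        out_first = nwcs_combine([m1], tie_policy="first")
        np.testing.assert_allclose(out_first.scores[0], [0.5, -1.0, -1.0])

    def test_method_order_is_irrelevant(self):
        rng = np.random.default_rng(6)
        mats = [cm_from(rng.dirichlet(np.ones(4), size=8), name=f"m{i}") for i in range(3)]
        np.testing.assert_allclose(
            nwcs_combine(mats).scores, nwcs_combine(mats[::-1]).scores
        )

    def test_unanimous_top_type_wins(self):
        rng = np.random.default_rng(7)
        rows = rng.dirichlet(np.ones(4), size=10)
        rows[:, 2] += 1.0  # make type 2 the unanimous top
        rows /= rows.sum(axis=1, keepdims=True)
        mats = [cm_from(rows * (0.5 + 0.5 * i / 3), name=f"m{i}", bounded=True) for i in range(3)]
        labels = deterministic_assignment(nwcs_combine(mats))
        assert (labels.labels == "T2").all()


class TestDeterministicAssignment:
    def test_argmax_row(self):
        lv = deterministic_assignment(cm_from([[0.2, 0.5, 0.3]]))
        assert lv.labels[0] == "T1"

    def test_tie_broken_by_taxonomy_order(self):
        lv = deterministic_assignment(cm_from([[0.5, 0.5, 0.0]]))
        assert lv.labels[0] == "T0"

    def test_zero_row_is_unassigned(self):
        lv = deterministic_assignment(cm_from([[0.0, 0.0, 0.0]]))
        assert lv.labels[0] == UNASSIGNED


class TestConsensusBeatsIndividuals:
    def test_both_strategies_exceed_mean_individual_accuracy(self, tissue, spec):
        _, _, truth = tissue
        mats = generate_confidences(
            truth, spec.subclasses, m=5,
            noise=NoiseModel(flip_probability=0.25, seed=21),
        )
        individual = [accuracy(deterministic_assignment(m), truth) for m in mats]
        mean_individual = float(np.mean(individual))
        gmcs_acc = accuracy(deterministic_assignment(gmcs_combine(mats)), truth)
        nwcs_acc = accuracy(deterministic_assignment(nwcs_combine(mats)), truth)
        assert gmcs_acc > mean_individual
        assert nwcs_acc > mean_individual
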