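"""Registration meta-algorithm: metric battery, rank transform, consensus
selection and export."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deskpipe import fixtures as fx
from deskpipe.irma import (
    CostMatrix,
    RankMatrix,
    default_battery,
    edi,
    evaluate_battery,
    export_parallel_coordinates,
    import_parallel_coordinates,
    rank_transform,
    select_best,
    woods,
)


@pytest.fixture(scope="module")
def reference():
    return fx.make_irma_reference(fx.FixtureConfig(seed=2))


class TestMetrics:
    def test_identical_candidate_scores_zero_on_every_metric(self, reference):
        """On a piecewise-constant reference, every default metric attains
        its documented optimum (0) for an identical candidate."""
        cm = evaluate_battery(reference, [("same", "f", reference.copy())])
        assert cm.values.shape == (1, 11)
        assert np.allclose(cm.values, 0.0, atol=1e-12)

    def test_constant_offset_gives_zero_edi_and_offset_squared_mse(self, reference):
        offset = reference + 25.0
        cm = evaluate_battery(reference, [("off", "f", offset)])
        row = dict(zip(cm.metric_ids, cm.values[0]))
        assert row["edi"] == 0.0  # single-bin difference histogram
        assert row["mse"] == pytest.approx(625.0)

    def test_noisier_copy_costs_at_least_as_much_on_every_metric(self):
        """Direct-computation oracle on 8x8x8 volumes: adding strictly more
        noise can never lower any implemented cost."""
        rng = np.random.default_rng(0)
        ref = fx.make_irma_reference(shape=(8, 8, 8))
        noise = rng.normal(0, 1, size=ref.shape)
        mild = ref + 5.0 * noise
        harsh = ref + 40.0 * noise
        cm = evaluate_battery(ref, [("mild", "f", mild.astype(np.float32)),
                                    ("harsh", "f", harsh.astype(np.float32))])
        assert np.all(cm.values[1] >= cm.values[0])

    def test_shape_mismatch_errors(self, reference):
        with pytest.raises(ValueError, match="shape"):
            evaluate_battery(reference, [("bad", "f", np.zeros((2, 2, 2)))])

    def test_woods_zero_requires_classwise_constant_candidate(self, reference):
        assert woods(reference, reference) == 0.0
        assert woods(reference, reference + np.linspace(0, 1, reference.size)
                     .reshape(reference.shape)) > 0.0

    def test_battery_size_is_configurable(self):
        assert len(default_battery(5)) == 5
        assert default_battery().ids()[:2] == ["edi", "woods"]


class TestRankTransform:
    def test_simple_column(self):
        cm = CostMatrix(["a", "b", "c"], ["f", "f", "f"], ["m"],
                        np.array([[0.1], [0.3], [0.2]]))
        rm = rank_transform(cm)
        assert list(rm.ranks[:, 0]) == [1.0, 3.0, 2.0]

    def test_all_equal_column_gets_average_rank(self):
        cm = CostMatrix(["a", "b", "c"], ["f"] * 3, ["m"], np.ones((3, 1)))
        rm = rank_transform(cm)
        assert np.allclose(rm.ranks[:, 0], 2.0)  # (n+1)/2

    def test_random_matrix_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.random((6, 4))
        cm = CostMatrix([f"i{k}" for k in range(6)], ["f"] * 6,
                        [f"m{j}" for j in range(4)], values)
        rm = rank_transform(cm)
        # brute-force oracle: rank = 1 + number of strictly smaller entries
        for j in range(4):
            col = values[:, j]
            for i in range(6):
                expected = 1 + np.sum(col < col[i]) + 0.5 * (np.sum(col == col[i]) - 1)
                assert rm.ranks[i, j] == pytest.approx(expected)

    def test_columns_are_permutations_up_to_ties(self):
        rng = np.random.default_rng(3)
        cm = CostMatrix([f"i{k}" for k in range(5)], ["f"] * 5, ["m0", "m1"],
                        rng.random((5, 2)))
        rm = rank_transform(cm)
        for j in range(2):
            assert sorted(rm.ranks[:, j]) == [1, 2, 3, 4, 5]

    def test_candidate_permutation_permutes_ranks_identically(self):
        rng = np.random.default_rng(11)
        values = rng.random((6, 3))
        ids = [f"i{k}" for k in range(6)]
        cm = CostMatrix(ids, ["f"] * 6, ["a", "b", "c"], values)
        perm = rng.permutation(6)
        cm_p = CostMatrix([ids[i] for i in perm], ["f"] * 6, ["a", "b", "c"],
                          values[perm])
        r, rp = rank_transform(cm), rank_transform(cm_p)
        assert np.allclose(r.ranks[perm], rp.ranks)


class TestSelectBest:
    def test_dominant_instance_is_selected(self):
        ranks = np.array([[1.0] * 5, [2.0] * 5, [3.0] * 5])
        rm = RankMatrix(["win", "mid", "lose"], ["f1", "f2", "f1"],
                        [f"m{j}" for j in range(5)], ranks)
        sel = select_best(rm)
        assert sel.instance_id == "win"

    def test_selection_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        costs = rng.random((5, 7))
        cm = CostMatrix([f"i{k}" for k in range(5)], ["f"] * 5,
                        [f"m{j}" for j in range(7)], costs)
        rm = rank_transform(cm)
        sel = select_best(rm)
        # brute force over all rows
        keys = [(np.median(rm.ranks[i]), rm.ranks[i].mean(), i) for i in range(5)]
        best = min(keys)
        assert sel.instance_id == rm.instance_ids[best[2]]

    def test_consistent_family_wins_despite_two_dissenting_metrics(self):
        """A rank structure with one family dominating 9 of 11 metrics while
        two metrics disagree: the consistent family must still rank first."""
        metric_ids = [f"m{j}" for j in range(9)] + ["edi", "woods"]
        rows, fams, ids = [], [], []
        rng = np.random.default_rng(4)
        for k in range(4):  # flirt: best on 9 metrics, worst on edi/woods
            ids.append(f"flirt-{k}")
            fams.append("flirt")
            rows.append([1 + k] * 9 + [13 + k, 13 + k])
        for fam_i, fam in enumerate(("air-linear", "air-warp", "minc-tracc")):
            for k in range(4):
                ids.append(f"{fam}-{k}")
                fams.append(fam)
                rows.append([5 + fam_i * 4 + k] * 9 + [1 + fam_i * 4 + k] * 2)
        rm = RankMatrix(ids, fams, metric_ids, np.array(rows, dtype=float))
        sel = select_best(rm)
        assert sel.family == "flirt"
        assert sel.family_order[0][0] == "flirt"

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_invariant_to_strictly_monotone_metric_transforms(self, seed):
        """Rank-based selection cannot change when each metric's costs are
        passed through its own strictly increasing transform."""
        rng = np.random.default_rng(seed)
        costs = rng.random((6, 5))
        ids = [f"i{k}" for k in range(6)]
        cm = CostMatrix(ids, ["f"] * 6, [f"m{j}" for j in range(5)], costs)
        transforms = [np.exp, lambda x: x ** 3, lambda x: 5 * x + 2,
                      np.tan, lambda x: np.log1p(x)]
        warped = np.column_stack(
            [transforms[j % len(transforms)](costs[:, j]) for j in range(5)]
        )
        cm2 = CostMatrix(ids, ["f"] * 6, cm.metric_ids, warped)
        assert select_best(rank_transform(cm)).instance_id == \
            select_best(rank_transform(cm2)).instance_id


class TestParallelCoordinates:
    def _rank_matrix(self):
        rng = np.random.default_rng(15)
        cm = CostMatrix([f"i{k}" for k in range(4)],
                        ["flirt", "flirt", "air-warp", "minc-tracc"],
                        [f"m{j}" for j in range(3)], rng.random((4, 3)))
        return rank_transform(cm)

    def test_round_trip_identity(self, tmp_path):
        rm = self._rank_matrix()
        path = export_parallel_coordinates(rm, str(tmp_path / "pc.csv"))
        back = import_parallel_coordinates(path)
        assert back.instance_ids == rm.instance_ids
        assert back.families == rm.families
        assert back.metric_ids == rm.metric_ids
        assert np.allclose(back.ranks, rm.ranks)

    def test_column_count_is_battery_plus_identity(self, tmp_path):
        rm = self._rank_matrix()
        path = export_parallel_coordinates(rm, str(tmp_path / "pc.csv"))
        header = open(path).readline().strip().split(",")
        assert len(header) == len(rm.metric_ids) + 2

    def test_empty_battery_errors(self, tmp_path):
        rm = RankMatrix(["a"], ["f"], [], np.zeros((1, 0)))
        with pytest.raises(ValueError, match="empty battery"):
            export_parallel_coordinates(rm, str(tmp_path / "x.csv"))


def test_family_quality_ordering_on_synthetic_candidates():
    """End to end on the packaged synthetic warps: the least-distorted family
    (flirt, by construction) wins the consensus."""
    config = fx.FixtureConfig(
        seed=6,
        irma_family_runs={"air-linear": 5, "air-warp": 5, "flirt": 5, "minc-tracc": 5},
    )
    ref = fx.make_irma_reference(config)
    cands = fx.make_irma_candidates(config)
    sel = select_best(rank_transform(evaluate_battery(ref, cands)))
    assert sel.family == "flirt"
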