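import numpy as np
import pytest

from barcodekit.abgd import (
    Partition,
    categorize_groups,
    detect_gap,
    partition_at_threshold,
    prior_series,
    recursive_partition,
    scan_priors,
    select_initial_partition,
)
from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.errors import ConfigError
from conftest import make_dataset


def _dm_from_matrix(labels, values):
    return DistanceMatrix(list(labels), np.asarray(values, float), "simple")


class TestPriorSeries:
    def test_geometric_three_steps(self):
        assert prior_series(0.001, 0.1, 3) == pytest.approx([0.001, 0.01, 0.1])

    def test_two_steps_endpoints(self):
        assert prior_series(0.001, 0.1, 2) == pytest.approx([0.001, 0.1])

    def test_default_ten_steps(self):
        s = prior_series()
        assert len(s) == 10
        assert s[0] == pytest.approx(0.001) and s[-1] == pytest.approx(0.1)

    def test_invalid_bounds_raise(self):
        with pytest.raises(ConfigError):
            prior_series(0.1, 0.001)
        with pytest.raises(ConfigError):
            prior_series(0.01, 0.1, steps=1)


class TestDetectGap:
    def test_clear_gap_midpoint_between_clusters(self):
        # dense below 0.01, dense above 0.06: the 0.05 jump dwarfs local gaps
        low = np.linspace(0.001, 0.01, 30)
        high = np.linspace(0.06, 0.09, 30)
        d = np.sort(np.concatenate([low, high]))
        thr = detect_gap(d, prior_p=0.02, X=1.5)
        assert thr is not None
        assert 0.01 < thr < 0.06

    def test_uniform_spacing_no_gap(self):
        d = np.linspace(0.0, 0.1, 50)
        assert detect_gap(d, prior_p=0.001, X=1.5) is None

    def test_all_below_prior_no_gap(self):
        d = np.linspace(0.001, 0.01, 20)
        assert detect_gap(d, prior_p=0.02, X=1.5) is None

    def test_fewer_than_two_distances(self):
        assert detect_gap([0.01], prior_p=0.001) is None
        assert detect_gap([], prior_p=0.001) is None


class TestPartitionAtThreshold:
    def test_threshold_below_all_singletons(self):
        ds = make_dataset(
            [("a", "S", "AAAA"), ("b", "S", "AATT"), ("c", "S", "TTTT")]
        )
        part = partition_at_threshold(distance_matrix(ds), 0.1)
        assert part.n_groups == 3

    def test_threshold_above_all_one_group(self):
        ds = make_dataset(
            [("a", "S", "AAAA"), ("b", "S", "AATT"), ("c", "S", "TTTT")]
        )
        part = partition_at_threshold(distance_matrix(ds), 1.0)
        assert part.n_groups == 1

    def test_planted_three_clusters(self):
        # hand-built matrix: intra <= 0.01, inter >= 0.06
        labels = ["a1", "a2", "b1", "b2", "c1", "c2"]
        v = np.full((6, 6), 0.08)
        np.fill_diagonal(v, 0.0)
        for i, j in [(0, 1), (2, 3), (4, 5)]:
            v[i, j] = v[j, i] = 0.01
        part = partition_at_threshold(_dm_from_matrix(labels, v), 0.03)
        assert sorted(sorted(g) for g in part.groups) == [
            ["a1", "a2"],
            ["b1", "b2"],
            ["c1", "c2"],
        ]

    def test_single_linkage_chains(self):
        # a-b and b-c close, a-c far: single linkage keeps them together
        labels = ["a", "b", "c"]
        v = np.array([[0, 0.01, 0.1], [0.01, 0, 0.01], [0.1, 0.01, 0]])
        part = partition_at_threshold(_dm_from_matrix(labels, v), 0.02)
        assert part.n_groups == 1

    def test_monotone_coarsening(self, planted):
        _, dm, _ = planted
        counts = [
            partition_at_threshold(dm, t).n_groups
            for t in np.linspace(0.0, 0.2, 15)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRecursivePartition:
    def test_no_gap_one_group(self):
        ds = make_dataset(
            [("a", "S", "AAAA"), ("b", "S", "AAAT"), ("c", "S", "AATT")]
        )
        part = recursive_partition(distance_matrix(ds), prior_p=0.001)
        assert part.n_groups == 1

    def test_single_record_one_singleton_group(self):
        dm = _dm_from_matrix(["only"], [[0.0]])
        part = recursive_partition(dm, prior_p=0.001)
        assert part.groups == [frozenset({"only"})]

    def test_two_level_hierarchy_recovers_three_groups(self):
        # cluster A = {a1,a2} vs cluster B = {b1..b4}; B itself contains two
        # subclusters separated by a second, smaller gap beyond the prior
        labels = ["a1", "a2", "b1", "b2", "b3", "b4"]
        v = np.zeros((6, 6))
        far, mid, near = 0.5, 0.12, 0.01
        coords = {"a1": 0, "a2": 1, "b1": 2, "b2": 3, "b3": 4, "b4": 5}
        for x in labels:
            for y in labels:
                if x == y:
                    continue
                ca, cb = coords[x], coords[y]
                if {ca, cb} <= {0, 1} or {ca, cb} <= {2, 3} or {ca, cb} <= {4, 5}:
                    v[ca, cb] = near
                elif {ca, cb} <= {2, 3, 4, 5}:
                    v[ca, cb] = mid
                else:
                    v[ca, cb] = far
        dm = _dm_from_matrix(labels, v)
        part = recursive_partition(dm, prior_p=0.001, X=1.5)
        # non-recursive oracle applied twice: split at the big gap, then
        # split the B group at the mid gap
        top = partition_at_threshold(dm, 0.3)
        assert top.n_groups == 2
        b_ids = ["b1", "b2", "b3", "b4"]
        sub = partition_at_threshold(dm.submatrix(b_ids), 0.05)
        assert sub.n_groups == 2
        assert part.n_groups == 3
        assert sorted(sorted(g) for g in part.groups) == [
            ["a1", "a2"],
            ["b1", "b2"],
            ["b3", "b4"],
        ]

    def test_partitions_are_exhaustive_and_disjoint(self, planted):
        ds, dm, _ = planted
        for prior in prior_series(0.001, 0.1, 5):
            part = recursive_partition(dm, prior)
            assert part.record_ids() == set(dm.labels)
            assert sum(len(g) for g in part.groups) == len(dm.labels)


class TestSelectInitialPartition:
    @staticmethod
    def _fake(prior, n):
        return Partition(
            prior, [frozenset({f"p{prior}g{i}"}) for i in range(n)], None
        )

    def test_modal_count_first_occurrence(self):
        parts = [
            self._fake(p, n)
            for p, n in zip([0.001, 0.002, 0.004, 0.008, 0.016], [9, 5, 5, 5, 2])
        ]
        assert select_initial_partition(parts).prior_p == 0.002

    def test_all_equal_smallest_prior(self):
        parts = [self._fake(p, 3) for p in [0.001, 0.01, 0.1]]
        assert select_initial_partition(parts).prior_p == 0.001

    def test_single_partition_identity(self):
        only = self._fake(0.01, 4)
        assert select_initial_partition([only]) is only

    def test_empty_raises(self):
        with pytest.raises(ConfigError):
            select_initial_partition([])


class TestCategorizeGroups:
    def _ds(self):
        return make_dataset(
            [
                ("a1", "A", "ACGT"),
                ("a2", "A", "ACGT"),
                ("b1", "B", "ACGT"),
                ("b2", "B", "ACGT"),
                ("c1", "C", "ACGT"),
            ]
        )

    def test_pure_exclusive_group_true(self):
        part = Partition(0.01, [frozenset({"a1", "a2"}), frozenset({"b1", "b2"}), frozenset({"c1"})], None)
        cats, summary = categorize_groups(part, self._ds())
        assert [c.tag for c in cats] == ["TRUE", "TRUE", "SINGLETON"]
        assert summary["pct_true_species"] == pytest.approx(100 * 2 / 3)

    def test_mixed_group_incorrect(self):
        part = Partition(
            0.01, [frozenset({"a1", "a2", "b1", "b2"}), frozenset({"c1"})], None
        )
        cats, _ = categorize_groups(part, self._ds())
        assert cats[0].tag == "INCORRECT"

    def test_mixed_split_groups_incorrect(self):
        part = Partition(
            0.01,
            [
                frozenset({"a1", "b1"}),
                frozenset({"a2", "b2"}),
                frozenset({"c1"}),
            ],
            None,
        )
        cats, _ = categorize_groups(part, self._ds())
        assert cats[0].tag == "INCORRECT" and cats[1].tag == "INCORRECT"

    def test_pure_split_species_ambiguous(self):
        ds = make_dataset(
            [("a1", "A", "ACGT"), ("a2", "A", "ACGT"), ("a3", "A", "ACGT"), ("a4", "A", "ACGT")]
        )
        part = Partition(
            0.01, [frozenset({"a1", "a2"}), frozenset({"a3", "a4"})], None
        )
        cats, summary = categorize_groups(part, ds)
        assert [c.tag for c in cats] == ["AMBIGUOUS", "AMBIGUOUS"]
        assert summary["pct_true_species"] == 0.0


class TestPlantedRecovery:
    def test_selected_partition_equals_species_partition(self, planted):
        ds, dm, _ = planted
        partitions = scan_priors(dm, p_min=0.001, p_max=0.1, steps=10, X=1.5)
        selected = select_initial_partition(partitions)
        truth = {
            frozenset(r.record_id for r in ds if r.species == sp)
            for sp in set(ds.species_labels)
        }
        assert set(selected.groups) == truth
        cats, summary = categorize_groups(selected, ds)
        assert all(c.tag == "TRUE" for c in cats)
        assert summary["pct_true_species"] == 100.0

    def test_group_count_non_increasing_over_priors(self, planted):
        _, dm, _ = planted
        partitions = scan_priors(dm, p_min=0.001, p_max=0.1, steps=10, X=1.5)
        counts = [p.n_groups for p in partitions]
        assert counts == sorted(counts, reverse=True)
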