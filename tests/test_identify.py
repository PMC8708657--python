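import itertools

import numpy as np
import pytest

from barcodekit.distances import distance_matrix
from barcodekit.errors import ComputationError
from barcodekit.identify import (
    all_species_barcodes,
    best_close_match,
    best_match,
    identify_all,
    intraspecific_distances,
    percentile_threshold,
    rollup_species,
)
from barcodekit.synth import SynthConfig, generate_dataset
from conftest import make_dataset
from oracles import brute_percentile


def _toy():
    # 4 records, 2 species; pairwise p-distances verifiable by hand (L=20)
    return make_dataset(
        [
            ("a1", "SpA", "AAAAAAAAAAAAAAAAAAAA"),
            ("a2", "SpA", "CAAAAAAAAAAAAAAAAAAA"),  # 0.05 from a1
            ("b1", "SpB", "TTTTTTTTTTAAAAAAAAAA"),  # 0.50 from a1
            ("b2", "SpB", "GTTTTTTTTTAAAAAAAAAA"),  # 0.05 from b1
        ]
    )


class TestIntraspecificDistances:
    def test_two_pairs(self):
        ds = _toy()
        dm = distance_matrix(ds)
        vals = intraspecific_distances(dm, ds)
        assert sorted(vals) == pytest.approx([0.05, 0.05])

    def test_all_singletons_error(self):
        ds = make_dataset([("a", "A", "ACGT"), ("b", "B", "ACGT")])
        with pytest.raises(ComputationError):
            intraspecific_distances(distance_matrix(ds), ds)

    def test_matches_brute_force_pair_scan(self):
        ds, dm, _ = None, None, None
        cfg = SynthConfig(n_species=3, members_per_species=3, seq_length=100, seed=7)
        ds, _ = generate_dataset(cfg)
        dm = distance_matrix(ds)
        expected = sorted(
            dm.get(r1.record_id, r2.record_id)
            for r1, r2 in itertools.combinations(ds.records, 2)
            if r1.species == r2.species
        )
        assert sorted(intraspecific_distances(dm, ds)) == pytest.approx(expected)


class TestPercentileThreshold:
    def test_constant_values(self):
        assert percentile_threshold([0, 0, 0, 0]) == 0

    def test_linear_interpolation_1_to_100(self):
        # frozen from the longhand order-statistic oracle
        values = list(range(1, 101))
        assert percentile_threshold(values, 95) == pytest.approx(95.05)
        assert percentile_threshold(values, 95) == pytest.approx(
            brute_percentile(values, 95)
        )

    def test_single_value(self):
        for q in (1, 50, 95, 100):
            assert percentile_threshold([0.37], q) == 0.37

    def test_empty_raises(self):
        with pytest.raises(ComputationError):
            percentile_threshold([])

    def test_agrees_with_oracle_on_random_values(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.random(rng.integers(2, 30)).tolist()
            q = float(rng.uniform(1, 100))
            assert percentile_threshold(vals, q) == pytest.approx(
                brute_percentile(vals, q)
            )


class TestBestMatch:
    def test_nearest_conspecific_correct(self):
        ds = _toy()
        dm = distance_matrix(ds)
        out = best_match(dm, ds, "a1")
        assert out.category == "Correct"
        assert out.best_match_ids == ("a2",)
        assert out.best_distance == pytest.approx(0.05)

    def test_singleton_forced_incorrect(self):
        ds = make_dataset(
            [("a", "A", "AAAA"), ("b", "B", "AAAT"), ("c", "B", "AATT")]
        )
        dm = distance_matrix(ds)
        assert best_match(dm, ds, "a").category == "Incorrect"

    def test_exact_tie_mixing_species_is_ambiguous(self):
        ds = make_dataset(
            [
                ("q", "A", "AAAA"),
                ("same", "A", "AAAT"),
                ("other", "B", "AATA"),
                ("far", "B", "TTTT"),
            ]
        )
        dm = distance_matrix(ds)
        out = best_match(dm, ds, "q")
        assert out.category == "Ambiguous"
        assert set(out.best_match_ids) == {"same", "other"}


class TestBestCloseMatch:
    def test_within_threshold_correct(self):
        ds = _toy()
        dm = distance_matrix(ds)
        assert best_close_match(dm, ds, "a1", 0.10).category == "Correct"

    def test_beyond_threshold_nomatch(self):
        ds = _toy()
        dm = distance_matrix(ds)
        out = best_close_match(dm, ds, "a1", 0.03)
        assert out.category == "NoMatch"
        assert out.best_match_ids == ()

    def test_threshold_zero_counts_zero_distance_neighbours(self, planted):
        ds, dm, _ = planted
        report = identify_all(dm, ds, criterion="BCM", threshold=0.0)
        n_nomatch = sum(1 for o in report.outcomes if o.category == "NoMatch")
        # brute force: records with no zero-distance neighbour
        expected = 0
        for i, rid in enumerate(dm.labels):
            d = np.delete(dm.values[i], i)
            if d.min() > 1e-12:
                expected += 1
        assert n_nomatch == expected


class TestAllSpeciesBarcodes:
    def test_all_conspecifics_close_correct(self):
        ds = make_dataset(
            [
                ("q", "A", "A" * 100),
                ("c1", "A", "A" * 100),  # 0.00
                ("c2", "A", "T" + "A" * 99),  # 0.01
                ("x", "B", "T" * 8 + "A" * 92),  # 0.08
            ]
        )
        dm = distance_matrix(ds)
        out = all_species_barcodes(dm, ds, "q", 0.03)
        assert out.category == "Correct"
        assert set(out.best_match_ids) == {"c1", "c2"}

    def test_interloping_allospecific_incorrect(self):
        ds = make_dataset(
            [
                ("q", "A", "A" * 100),
                ("c1", "A", "TT" + "A" * 98),  # conspecific at 0.02
                ("x", "B", "T" + "A" * 99),  # allospecific at 0.01
            ]
        )
        dm = distance_matrix(ds)
        assert all_species_barcodes(dm, ds, "q", 0.03).category == "Incorrect"

    def test_singleton_never_correct(self):
        ds = make_dataset(
            [
                ("q", "A", "A" * 100),
                ("x1", "B", "T" + "A" * 99),
                ("x2", "B", "TT" + "A" * 98),
            ]
        )
        dm = distance_matrix(ds)
        assert all_species_barcodes(dm, ds, "q", 0.03).category == "Incorrect"
        # with nothing in reach the singleton gets NoMatch instead
        assert all_species_barcodes(dm, ds, "q", 0.001).category == "NoMatch"

    def test_allospecific_tie_with_farthest_conspecific_ambiguous(self):
        ds = make_dataset(
            [
                ("q", "A", "A" * 100),
                ("c1", "A", "T" + "A" * 99),  # 0.01
                ("x", "B", "A" * 99 + "T"),  # 0.01 exact tie with c1
            ]
        )
        dm = distance_matrix(ds)
        assert all_species_barcodes(dm, ds, "q", 0.03).category == "Ambiguous"


class TestRollupSpecies:
    def _roll(self, cats_by_species):
        entries = []
        outcomes = []
        from barcodekit.identify import IdentificationOutcome

        i = 0
        for sp, cats in cats_by_species.items():
            for cat in cats:
                rid = f"r{i}"
                i += 1
                entries.append((rid, sp, "ACGT"))
                outcomes.append(
                    IdentificationOutcome(rid, "BM", cat, ("x",), 0.0)
                )
        return rollup_species(outcomes, make_dataset(entries))

    def test_all_correct_counts_both(self):
        assert self._roll({"A": ["Correct", "Correct"]}) == (100.0, 100.0)

    def test_ambiguous_vetoes_true(self):
        assert self._roll({"A": ["Correct", "Ambiguous"]}) == (100.0, 0.0)

    def test_nomatch_does_not_veto_true(self):
        assert self._roll({"A": ["Correct", "NoMatch"]}) == (100.0, 100.0)


class TestProperties:
    def test_planted_gap_all_criteria_100pct(self, planted):
        ds, dm, _ = planted
        for criterion in ("BM", "BCM", "ASB"):
            report = identify_all(dm, ds, criterion=criterion, threshold=0.03)
            assert report.pct_correct == 100.0
            assert report.true_species_pct == 100.0

    def test_sequence_percentages_sum_to_100(self, singleton_rich):
        ds, dm, _ = singleton_rich
        for criterion in ("BM", "BCM", "ASB"):
            r = identify_all(dm, ds, criterion=criterion, threshold=0.03)
            total = r.pct_correct + r.pct_incorrect + r.pct_ambiguous + r.pct_nomatch
            assert total == pytest.approx(100.0)

    def test_bcm_correct_never_exceeds_bm(self, singleton_rich):
        ds, dm, _ = singleton_rich
        bm = identify_all(dm, ds, criterion="BM")
        bcm = identify_all(dm, ds, criterion="BCM", threshold=0.01)
        assert bcm.pct_correct <= bm.pct_correct

    def test_outcome_invariant_to_record_order(self):
        entries = [
            ("a1", "SpA", "AAAAAAAAAAAAAAAAAAAA"),
            ("a2", "SpA", "CAAAAAAAAAAAAAAAAAAA"),
            ("b1", "SpB", "TTTTTTTTTTAAAAAAAAAA"),
            ("b2", "SpB", "GTTTTTTTTTAAAAAAAAAA"),
        ]
        base = {
            o.record_id: o.category
            for o in identify_all(
                distance_matrix(make_dataset(entries)), make_dataset(entries), "BM"
            ).outcomes
        }
        shuffled = entries[::-1]
        other = {
            o.record_id: o.category
            for o in identify_all(
                distance_matrix(make_dataset(shuffled)), make_dataset(shuffled), "BM"
            ).outcomes
        }
        assert base == other
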