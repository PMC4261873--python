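import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vennkit as vk
from vennkit.errors import ListLimitError, QueryError, VennKitError
from oracles import bitmask_partition, brute_force_value_sums, random_lists

identifiers = st.text(
    alphabet=st.characters(min_codepoint=48, max_codepoint=122), min_size=1, max_size=6
)
small_collections = st.lists(
    st.lists(identifiers, max_size=12), min_size=1, max_size=6
)


def _series_from(lists):
    return [vk.VennSeries.from_raw(f"l{i}", lst) for i, lst in enumerate(lists)]


class TestComputePartition:
    def test_worked_example_memberships(self, two_sample_table):
        t = two_sample_table
        assert t.counts == {"A": 3, "B": 2, "AB": 4}
        assert set(t.elements["A"]) == {"Otu3", "Otu4", "Otu6"}
        assert set(t.elements["B"]) == {"Otu8", "Otu9"}
        assert set(t.elements["AB"]) == {"Otu1", "Otu2", "Otu5", "Otu7"}

    def test_single_list_degenerate(self):
        table = vk.compute_partition(_series_from([["a", "b", "c"]]))
        assert table.counts == {"A": 3}

    def test_seven_lists_hit_the_cap(self):
        with pytest.raises(ListLimitError):
            vk.compute_partition(_series_from([["x"]] * 7))

    def test_matches_bitmask_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            lists = random_lists(rng, n)
            table = vk.compute_partition(_series_from(lists))
            expected = bitmask_partition(lists)
            for key in table.regions():
                assert set(table.elements[key]) == expected.get(key, set())

    @given(small_collections)
    def test_partition_and_inclusion_invariants(self, lists):
        series = _series_from(lists)
        table = vk.compute_partition(series)
        union = set().union(*(set(s.data) for s in series))
        regions = [set(table.elements[k]) for k in table.regions()]
        # pairwise disjoint and exhaustive
        assert sum(len(r) for r in regions) == len(set().union(*regions, set()))
        assert set().union(*regions, set()) == union
        # each list's size equals the sum of counts of regions containing it
        for lab, s in zip(table.labels, series):
            assert len(s.data) == sum(
                table.counts[k] for k in table.regions() if lab in k
            )

    def test_empty_lists_yield_all_zero_regions(self):
        table = vk.compute_partition(
            [vk.VennSeries("a", ()), vk.VennSeries("b", ())]
        )
        assert all(c == 0 for c in table.counts.values())


class TestAggregateCountValues:
    def test_worked_example_sums(self, two_sample_values_series):
        series = two_sample_values_series
        table = vk.compute_partition(series)
        sums = vk.aggregate_count_values(series, table)
        assert sums.counts == {"A": 328.0, "B": 54.0, "AB": 534.0}
        assert sums.mode == "value_sum"

    def test_all_zero_values(self):
        series = [
            vk.VennSeries("a", ("x", "y"), (0.0, 0.0)),
            vk.VennSeries("b", ("y",), (0.0,)),
        ]
        sums = vk.aggregate_count_values(series, vk.compute_partition(series))
        assert all(v == 0 for v in sums.counts.values())

    def test_missing_values_rejected(self, two_sample_series):
        table = vk.compute_partition(two_sample_series)
        with pytest.raises(VennKitError):
            vk.aggregate_count_values(two_sample_series, table)

    def test_conservation_against_brute_force(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 7))
            lists = random_lists(rng, n, max_elements=40)
            values = [
                [float(v) for v in rng.integers(0, 100, size=len(lst))]
                for lst in lists
            ]
            series = [
                vk.VennSeries.from_raw(f"l{i}", lst, vals)
                for i, (lst, vals) in enumerate(zip(lists, values))
            ]
            table = vk.compute_partition(series)
            sums = vk.aggregate_count_values(series, table)
            expected = brute_force_value_sums(
                [list(s.data) for s in series],
                [list(s.values) for s in series],
            )
            for key in table.regions():
                assert sums.counts[key] == pytest.approx(expected.get(key, 0.0))
            grand = sum(v for s in series for v in s.values)
            assert sum(sums.counts.values()) == pytest.approx(grand)


class TestStats:
    def test_worked_example_sizes(self, two_sample_series):
        assert vk.list_size_stats(two_sample_series) == [7, 6]

    def test_empty_list_size_zero(self):
        assert vk.list_size_stats([vk.VennSeries("a", ())]) == [0]

    def test_worked_example_distribution(self, two_sample_table):
        assert vk.shared_distribution(two_sample_table) == {1: 5, 2: 4}

    def test_single_list_mass_at_one(self):
        table = vk.compute_partition([vk.VennSeries("a", ("x", "y"))])
        assert vk.shared_distribution(table) == {1: 2}

    def test_distribution_totals_union_and_tracks_new_element(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            lists = random_lists(rng, n, max_elements=50)
            table = vk.compute_partition(_series_from(lists))
            dist = vk.shared_distribution(table)
            union = set().union(*(set(lst) for lst in lists))
            assert sum(dist.values()) == len(union)
            # adding one brand-new element to one list increments the k=1 bin
            lists2 = [list(lst) for lst in lists]
            lists2[0].append("zzz_unique")
            dist2 = vk.shared_distribution(
                vk.compute_partition(_series_from(lists2))
            )
            assert dist2[1] == dist[1] + 1

    def test_value_sum_table_rejected(self, two_sample_values_series):
        series = two_sample_values_series
        sums = vk.aggregate_count_values(series, vk.compute_partition(series))
        with pytest.raises(VennKitError):
            vk.shared_distribution(sums)


class TestSearch:
    def test_exact_hit(self, two_sample_table):
        assert vk.search_identifiers(two_sample_table, "Otu8") == [("Otu8", "B")]

    def test_no_match(self, two_sample_table):
        assert vk.search_identifiers(two_sample_table, "zzz") == []

    def test_case_insensitive_substring_matches_all(self, two_sample_table):
        matches = vk.search_identifiers(two_sample_table, "otu")
        assert len(matches) == 9
        oracle = bitmask_partition(
            [
                ["Otu1", "Otu2", "Otu3", "Otu4", "Otu5", "Otu6", "Otu7"],
                ["Otu1", "Otu2", "Otu5", "Otu7", "Otu8", "Otu9"],
            ]
        )
        region_of = {el: key for key, els in oracle.items() for el in els}
        for ident, key in matches:
            assert region_of[ident] == key

    def test_empty_query_rejected(self, two_sample_table):
        with pytest.raises(QueryError):
            vk.search_identifiers(two_sample_table, "")
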