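"""Region coding: hierarchy expansion, matrix building and merge rules."""

import numpy as np
import pytest

from biogeofit.regions import (
    AreaHierarchy, OccurrenceTable, RegionCodingError, RegionGeography,
    RegionMatrix, build_region_matrix, code_regions, expand_to_finest,
    merge_autapomorphic_regions, merge_identical_regions,
)


@pytest.fixture
def chain_geo():
    """Five regions on a line with unit spacing."""
    names = ["r1", "r2", "r3", "r4", "r5"]
    pairs = [(names[i], names[j], float(j - i))
             for i in range(5) for j in range(i + 1, 5)]
    return RegionGeography.from_pairs(pairs, adjacency_threshold=1.0)


class TestExpandToFinest:
    def test_larger_region_broken_into_subregions(self):
        occ = OccurrenceTable([("A", "NorthAmerica"), ("B", "USA")])
        hier = AreaHierarchy({"NorthAmerica": {"USA", "Canada"}})
        sets = expand_to_finest(occ, hier)
        assert sets == {"A": {"USA", "Canada"}, "B": {"USA"}}

    def test_leaf_records_unchanged(self):
        occ = OccurrenceTable([("A", "x"), ("B", "y")])
        hier = AreaHierarchy({})
        assert expand_to_finest(occ, hier) == {"A": {"x"}, "B": {"y"}}

    def test_three_level_recursion(self):
        occ = OccurrenceTable([("T", "X")])
        hier = AreaHierarchy({"X": {"Y", "z"}, "Y": {"y1", "y2"}})
        assert expand_to_finest(occ, hier)["T"] == {"y1", "y2", "z"}

    def test_unknown_area_rejected(self):
        occ = OccurrenceTable([("A", "Atlantis")])
        hier = AreaHierarchy({"X": {"x1", "x2"}}, areas={"X", "x1", "x2"})
        with pytest.raises(RegionCodingError, match="Atlantis"):
            expand_to_finest(occ, hier)

    def test_cyclic_hierarchy_rejected(self):
        with pytest.raises(RegionCodingError, match="cycle"):
            AreaHierarchy({"X": {"Y"}, "Y": {"X"}})


class TestBuildMatrix:
    def test_basic_scoring(self):
        m = build_region_matrix({"A": {"r1"}, "B": {"r1", "r2"}})
        assert m.regions == ["r1", "r2"]
        assert m.entries.tolist() == [[1, 0], [1, 1]]
        assert m.merge_log == []

    def test_disjoint_taxa_identity_pattern(self):
        m = build_region_matrix({"A": {"r1"}, "B": {"r2"}, "C": {"r3"}})
        assert m.entries.sum() == 3
        assert (m.entries.sum(axis=0) == 1).all()

    def test_single_taxon_rejected(self):
        with pytest.raises(RegionCodingError):
            build_region_matrix({"A": {"r1"}})


class TestMergeIdentical:
    def test_adjacent_duplicates_merge(self, chain_geo):
        m = RegionMatrix(["A", "B"], ["r1", "r2"],
                         np.array([[1, 1], [1, 1]]))
        merged = merge_identical_regions(m, chain_geo)
        assert merged.n_regions == 1
        assert merged.regions == ["r1+r2"]
        assert merged.merge_log[0]["rule"] == "identical-adjacent"

    def test_empty_row_rejected(self):
        with pytest.raises(RegionCodingError, match="nowhere"):
            RegionMatrix(["A", "B"], ["r1", "r2", "r3"],
                         np.array([[1, 1, 1], [0, 0, 0]]))

    def test_chain_of_three_collapses(self, chain_geo):
        m = RegionMatrix(["A", "B"], ["r1", "r2", "r3", "r4"],
                         np.array([[1, 1, 1, 0], [0, 0, 0, 1]]))
        merged = merge_identical_regions(m, chain_geo)
        assert merged.n_regions == 2
        assert "r1+r2+r3" in merged.regions
        assert len(merged.merge_log) == 2

    def test_distinct_columns_untouched(self, chain_geo):
        m = RegionMatrix(["A", "B"], ["r1", "r2"],
                         np.array([[1, 0], [1, 1]]))
        merged = merge_identical_regions(m, chain_geo)
        assert merged.entries.tolist() == m.entries.tolist()
        assert merged.merge_log == []

    def test_nonadjacent_duplicates_still_merge(self, chain_geo):
        # r1 and r4 identical but 3 apart; r2, r3 distinct fillers
        m = RegionMatrix(
            ["A", "B", "C"], ["r1", "r2", "r3", "r4"],
            np.array([[1, 1, 0, 1], [0, 1, 1, 0], [1, 0, 1, 1]]))
        merged = merge_identical_regions(m, chain_geo)
        assert merged.n_regions == 3
        assert any(e.get("rule") == "nonadjacent-duplicate"
                   for e in merged.merge_log)

    def test_coverage_conserved_through_identical_merges(self, chain_geo):
        m = RegionMatrix(["A", "B"], ["r1", "r2", "r3"],
                         np.array([[1, 1, 0], [0, 0, 1]]))
        merged = merge_identical_regions(m, chain_geo)
        covered = {
            taxon: frozenset().union(*(
                merged.constituents[r] for j, r in enumerate(merged.regions)
                if merged.entries[i, j]))
            for i, taxon in enumerate(merged.taxa)
        }
        assert covered == {"A": {"r1", "r2"}, "B": {"r3"}}


class TestMergeAutapomorphic:
    def test_single_presence_absorbed(self, chain_geo):
        m = RegionMatrix(
            ["A", "B", "C", "D"], ["r1", "r2"],
            np.array([[1, 1], [0, 1], [0, 1], [0, 1]]))
        # r1 held only by A; nearest neighbour r2 -> OR gives duplicate -> dedup
        merged = merge_autapomorphic_regions(m, chain_geo)
        assert merged.n_regions == 1

    def test_no_singles_is_identity(self, chain_geo):
        m = RegionMatrix(["A", "B", "C", "D"], ["r1", "r2"],
                         np.array([[1, 0], [1, 0], [0, 1], [0, 1]]))
        merged = merge_autapomorphic_regions(m, chain_geo)
        assert merged.entries.tolist() == m.entries.tolist()

    def test_fixpoint_has_no_singles_or_duplicates(self, chain_geo):
        rng = np.random.default_rng(3)
        for _ in range(25):
            entries = rng.integers(0, 2, size=(5, 5)).astype(np.int8)
            entries[entries.sum(axis=1) == 0, 0] = 1
            m = RegionMatrix([f"t{i}" for i in range(5)],
                             ["r1", "r2", "r3", "r4", "r5"], entries)
            merged = merge_autapomorphic_regions(
                merge_identical_regions(m, chain_geo), chain_geo)
            cols = [tuple(merged.entries[:, j]) for j in range(merged.n_regions)]
            assert len(set(cols)) == len(cols)
            if merged.n_regions > 1:
                assert (merged.entries.sum(axis=0) != 1).all()


class TestCodeRegions:
    @pytest.fixture
    def toy_study(self):
        """Five taxa over a nested hierarchy of six finest areas on a chain."""
        occ = OccurrenceTable([
            ("sp1", "West"), ("sp2", "w1"), ("sp2", "w2"), ("sp3", "w3"),
            ("sp3", "e1"), ("sp4", "East"), ("sp5", "e3"),
        ])
        hier = AreaHierarchy({"West": {"w1", "w2", "w3"},
                              "East": {"e1", "e2", "e3"}})
        names = ["w1", "w2", "w3", "e1", "e2", "e3"]
        pairs = [(names[i], names[j], float(j - i))
                 for i in range(6) for j in range(i + 1, 6)]
        geo = RegionGeography.from_pairs(pairs, adjacency_threshold=1.0)
        return occ, hier, geo

    def test_pipeline_invariants(self, toy_study):
        m = code_regions(*toy_study)
        assert not m.untestable
        cols = [tuple(m.entries[:, j]) for j in range(m.n_regions)]
        assert len(set(cols)) == len(cols)
        assert (m.entries.sum(axis=0) != 1).all() or m.n_regions == 1
        assert (m.entries.sum(axis=1) >= 1).all()

    def test_cosmopolitan_clade_untestable(self):
        occ = OccurrenceTable([(t, r) for t in ("A", "B", "C")
                               for r in ("r1", "r2")])
        hier = AreaHierarchy({})
        geo = RegionGeography.from_pairs([("r1", "r2", 1.0)])
        m = code_regions(occ, hier, geo)
        assert m.untestable

    def test_idempotence(self, toy_study):
        m = code_regions(*toy_study)
        occ2 = OccurrenceTable([
            (taxon, region)
            for i, taxon in enumerate(m.taxa)
            for j, region in enumerate(m.regions) if m.entries[i, j]
        ])
        hier2 = AreaHierarchy({})
        pairs = []
        regions = m.regions
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                _, _, geo = toy_study
                pairs.append((regions[i], regions[j],
                              geo.get(m.constituents[regions[i]],
                                      m.constituents[regions[j]])))
        geo2 = RegionGeography.from_pairs(pairs)
        m2 = code_regions(occ2, hier2, geo2)
        assert sorted(map(tuple, m2.entries.T)) == sorted(map(tuple, m.entries.T))

    def test_record_order_invariance(self, toy_study):
        occ, hier, geo = toy_study
        m1 = code_regions(occ, hier, geo)
        occ_rev = OccurrenceTable(list(reversed(occ.records)))
        m2 = code_regions(occ_rev, hier, geo)
        cols1 = sorted(map(tuple, (m1.entries[np.argsort(m1.taxa)]).T))
        cols2 = sorted(map(tuple, (m2.entries[np.argsort(m2.taxa)]).T))
        assert cols1 == cols2

    def test_missing_distance_rejected(self):
        occ = OccurrenceTable([("A", "r1"), ("B", "r1"), ("B", "r2"), ("A", "r3")])
        hier = AreaHierarchy({})
        geo = RegionGeography.from_pairs([("r1", "r2", 1.0)])  # r3 uncovered
        with pytest.raises(RegionCodingError, match="distance"):
            code_regions(occ, hier, geo)
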