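import numpy as np
import pytest
from Bio import Phylo
from io import StringIO

from sgbkit.binning import (
    NOVEL,
    BinCatalog,
    assign_to_catalog,
    build_hierarchy,
    classify_sgb,
    cluster_genomes,
    make_sgbs,
    medoid,
    upgma_newick,
)
from sgbkit.errors import ArgumentError, ConsistencyError
from sgbkit.io_formats import SequenceRecord
from sgbkit.sketching import DistanceMatrix, build_sketch
from sgbkit.synthetic import evolve_genome, generate_root_genome


def dm_from(ids, pairs):
    n = len(ids)
    values = np.zeros((n, n))
    index = {g: i for i, g in enumerate(ids)}
    for (a, b), d in pairs.items():
        values[index[a], index[b]] = values[index[b], index[a]] = d
    return DistanceMatrix(tuple(ids), values)


ABC = dm_from(["A", "B", "C"], {("A", "B"): 0.02, ("A", "C"): 0.30, ("B", "C"): 0.30})


class TestClusterGenomes:
    def test_all_distant_gives_singletons(self):
        dm = dm_from(["A", "B", "C"], {("A", "B"): 0.5, ("A", "C"): 0.6, ("B", "C"): 0.7})
        assert cluster_genomes(dm, 0.05) == [["A"], ["B"], ["C"]]

    def test_pair_merges_below_threshold(self):
        # hand-computed average linkage: A,B merge at 0.02; C stays out at 0.30
        assert cluster_genomes(ABC, 0.05) == [["A", "B"], ["C"]]

    def test_all_merge_at_loose_threshold(self):
        assert cluster_genomes(ABC, 0.35) == [["A", "B", "C"]]

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(12)]
        raw = rng.uniform(0, 1, size=(12, 12))
        values = np.triu(raw, 1)
        values = values + values.T
        dm = DistanceMatrix(tuple(ids), values)
        for t in (0.1, 0.4, 0.8):
            partition = cluster_genomes(dm, t)
            flat = [g for cluster in partition for g in cluster]
            assert sorted(flat) == sorted(ids)

    def test_threshold_monotonicity(self):
        """The partition at a tighter threshold refines the looser one."""
        rng = np.random.default_rng(5)
        points = rng.uniform(0, 1, size=(15, 2))
        values = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        values = np.clip(values / values.max(), 0, 1)
        np.fill_diagonal(values, 0)
        dm = DistanceMatrix(tuple(f"g{i}" for i in range(15)), values)
        previous = None
        for t in (0.05, 0.15, 0.30, 0.60):
            clusters = [set(c) for c in cluster_genomes(dm, t)]
            if previous is not None:
                for fine in previous:
                    assert any(fine <= coarse for coarse in clusters)
            previous = clusters

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ArgumentError):
            cluster_genomes(ABC, 0.0)


class TestMedoid:
    def test_singleton(self):
        assert medoid(ABC, ["B"]) == "B"

    def test_central_member_wins(self):
        dm = dm_from(
            ["A", "B", "C"],
            {("A", "B"): 0.4, ("A", "C"): 0.1, ("B", "C"): 0.1},
        )
        # sums: A=0.5, B=0.5, C=0.2 -> C
        assert medoid(dm, ["A", "B", "C"]) == "C"

    def test_tie_breaks_lexicographically(self):
        dm = dm_from(["A", "B"], {("A", "B"): 0.3})
        assert medoid(dm, ["B", "A"]) == "A"

    def test_empty_member_list_rejected(self):
        with pytest.raises(ArgumentError):
            medoid(ABC, [])


class TestClassifySgb:
    @pytest.mark.parametrize(
        "sources,expected",
        [
            ({"r1": "reference", "m1": "nhp_wild"}, "kSGB"),
            ({"h1": "human_westernized", "m1": "nhp_wild"}, "uSGB"),
            ({"h1": "human_nonwesternized"}, "uSGB"),
            ({"m1": "nhp_wild", "m2": "nhp_captive"}, "pSGB"),
        ],
    )
    def test_ladder(self, sources, expected):
        assert classify_sgb(list(sources), sources) == expected

    def test_unknown_genome_rejected(self):
        with pytest.raises(ConsistencyError):
            classify_sgb(["ghost"], {})

    def test_classification_is_exhaustive(self):
        categories = [
            "nhp_wild",
            "nhp_captive",
            "human_westernized",
            "human_nonwesternized",
            "reference",
        ]
        for a in categories:
            for b in categories:
                cls = classify_sgb(["x", "y"], {"x": a, "y": b})
                assert cls in {"kSGB", "uSGB", "pSGB"}


class TestHierarchy:
    def _sgbs(self, dm, sources):
        return make_sgbs(dm, sources, threshold=0.05)

    def test_close_medoids_share_ggb(self):
        dm = dm_from(["A", "B"], {("A", "B"): 0.10})
        sources = {"A": "nhp_wild", "B": "nhp_wild"}
        catalog = build_hierarchy(self._sgbs(dm, sources), dm, sources)
        assert len(catalog.at_level("SGB")) == 2
        assert len(catalog.at_level("GGB")) == 1
        assert len(catalog.at_level("FGB")) == 1

    def test_mid_distance_splits_ggb_not_fgb(self):
        dm = dm_from(["A", "B"], {("A", "B"): 0.25})
        sources = {"A": "nhp_wild", "B": "nhp_wild"}
        catalog = build_hierarchy(self._sgbs(dm, sources), dm, sources)
        assert len(catalog.at_level("GGB")) == 2
        assert len(catalog.at_level("FGB")) == 1

    def test_single_sgb_chains_parents(self):
        dm = dm_from(["A"], {})
        sources = {"A": "nhp_wild"}
        catalog = build_hierarchy(self._sgbs(dm, sources), dm, sources)
        (sgb,), (ggb,), (fgb,) = (
            catalog.at_level("SGB"),
            catalog.at_level("GGB"),
            catalog.at_level("FGB"),
        )
        assert sgb.parent_bin_id == ggb.bin_id
        assert ggb.parent_bin_id == fgb.bin_id
        assert fgb.parent_bin_id is None

    def test_nesting_invariant_on_cohort(self, cohort_bins):
        """All members of one SGB share that SGB's GGB and FGB."""
        catalog = cohort_bins["catalog"]
        ggb_of = {}
        for ggb in catalog.at_level("GGB"):
            for g in ggb.member_ids:
                ggb_of[g] = ggb.bin_id
        fgb_of = {}
        for fgb in catalog.at_level("FGB"):
            for g in fgb.member_ids:
                fgb_of[g] = fgb.bin_id
        for sgb in catalog.at_level("SGB"):
            assert len({ggb_of[g] for g in sgb.member_ids}) == 1
            assert len({fgb_of[g] for g in sgb.member_ids}) == 1
            assert sgb.parent_bin_id == ggb_of[sgb.member_ids[0]]

    def test_nonincreasing_thresholds_rejected(self):
        dm = dm_from(["A"], {})
        sources = {"A": "nhp_wild"}
        with pytest.raises(ArgumentError):
            build_hierarchy(
                self._sgbs(dm, sources), dm, sources,
                ggb_threshold=0.30, fgb_threshold=0.15,
            )


@pytest.fixture(scope="module")
def small_catalog():
    root = generate_root_genome(20_000, 0.5, seed=21)
    far = generate_root_genome(20_000, 0.5, seed=22, genome_id="far")
    members = [
        SequenceRecord("c1", root.sequence),
        evolve_genome(root, 0.01, seed=23, genome_id="c2"),
        SequenceRecord("far1", far.sequence),
    ]
    sketches = [build_sketch([m], genome_id=m.id) for m in members]
    from sgbkit.sketching import pairwise_distances

    dm = pairwise_distances(sketches)
    sources = {m.id: "nhp_wild" for m in members}
    catalog = build_hierarchy(make_sgbs(dm, sources), dm, sources)
    return {"root": root, "sketches": sketches, "catalog": catalog}


class TestAssignment:
    def test_identical_mag_assigned_at_zero(self, small_catalog):
        mag = build_sketch(
            [SequenceRecord("new", small_catalog["root"].sequence)], genome_id="new"
        )
        a = assign_to_catalog(
            mag, small_catalog["sketches"], small_catalog["catalog"], 0.05
        )
        assert a.min_distance == 0.0
        assert a.assigned_bin_id != NOVEL
        assert a.nearest_member_id == "c1"

    def test_distant_mag_is_novel(self, small_catalog):
        stranger = generate_root_genome(20_000, 0.5, seed=99, genome_id="new")
        mag = build_sketch([stranger], genome_id="new")
        a = assign_to_catalog(
            mag, small_catalog["sketches"], small_catalog["catalog"], 0.05
        )
        assert a.assigned_bin_id == NOVEL
        assert a.min_distance > 0.05

    def test_three_percent_divergent_mag_assigned(self, small_catalog):
        child = evolve_genome(small_catalog["root"], 0.03, seed=31, genome_id="new")
        mag = build_sketch([child], genome_id="new")
        a = assign_to_catalog(
            mag, small_catalog["sketches"], small_catalog["catalog"], 0.05
        )
        assert a.assigned_bin_id != NOVEL
        assert a.min_distance == pytest.approx(0.03, abs=0.01)

    def test_looser_threshold_never_increases_novelty(self, small_catalog):
        rng = np.random.default_rng(17)
        mags = [
            evolve_genome(small_catalog["root"], d, seed=int(rng.integers(2**31)),
                          genome_id=f"q{i}")
            for i, d in enumerate((0.02, 0.06, 0.12, 0.25))
        ]
        novel = {}
        for t in (0.05, 0.10):
            novel[t] = sum(
                assign_to_catalog(
                    build_sketch([m], genome_id=m.id),
                    small_catalog["sketches"],
                    small_catalog["catalog"],
                    t,
                ).assigned_bin_id
                == NOVEL
                for m in mags
            )
        assert novel[0.10] <= novel[0.05]

    def test_empty_catalog_rejected(self, small_catalog):
        empty = BinCatalog(bins=(), genome_sources={})
        mag = build_sketch(
            [SequenceRecord("new", small_catalog["root"].sequence)], genome_id="new"
        )
        with pytest.raises(ArgumentError):
            assign_to_catalog(mag, small_catalog["sketches"], empty, 0.05)


class TestUpgmaNewick:
    def test_two_leaves_exact(self):
        dm = dm_from(["A", "B"], {("A", "B"): 0.1})
        assert upgma_newick(dm) == "(A:0.05,B:0.05);"

    def test_three_leaves_ultrametric(self):
        dm = dm_from(
            ["A", "B", "C"], {("A", "B"): 0.1, ("A", "C"): 0.4, ("B", "C"): 0.4}
        )
        tree = Phylo.read(StringIO(upgma_newick(dm)), "newick")
        depths = tree.depths()
        leaf_depths = {t.name: d for t, d in depths.items() if t.name}
        assert set(leaf_depths) == {"A", "B", "C"}
        assert len({round(d, 9) for d in leaf_depths.values()}) == 1

    def test_identical_genomes_zero_branches(self):
        dm = dm_from(["A", "B"], {("A", "B"): 0.0})
        tree = Phylo.read(StringIO(upgma_newick(dm)), "newick")
        assert all(
            (c.branch_length or 0) == 0 for c in tree.find_clades() if c.name
        )

    def test_single_leaf_rejected(self):
        with pytest.raises(ArgumentError):
            upgma_newick(dm_from(["A"], {}))
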