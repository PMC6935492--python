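import numpy as np
import pytest

from sgbkit.errors import ArgumentError, UndefinedGainError
from sgbkit.io_formats import ReadRecord
from sgbkit.mappability import (
    build_index,
    host_filter,
    incremental_map,
    mappability_gain,
    pseudo_map_read,
    qc_reads,
    run_mappability,
    subsample_reads,
)
from sgbkit.synthetic import generate_root_genome, simulate_reads

FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _read(seq, quality=30, rid="r"):
    return ReadRecord(rid, seq, (quality,) * len(seq))


@pytest.fixture(scope="module")
def genome():
    return generate_root_genome(20_000, 0.5, seed=8, genome_id="g1")


@pytest.fixture(scope="module")
def index(genome):
    return build_index("reference_genomes", [genome])


class TestSubsample:
    def test_one_percent_of_thousand(self):
        reads = [_read("ACGT" * 25, rid=f"r{i}") for i in range(1000)]
        assert len(subsample_reads(reads, 0.01, seed=1)) == 10

    def test_full_fraction_is_identity(self):
        reads = [_read("ACGT" * 25, rid=f"r{i}") for i in range(7)]
        assert subsample_reads(reads, 1.0, seed=1) == reads

    def test_floor_can_reach_zero(self):
        reads = [_read("ACGT" * 25, rid=f"r{i}") for i in range(50)]
        assert subsample_reads(reads, 0.01, seed=1) == []

    def test_deterministic_and_order_preserving(self):
        reads = [_read("ACGT" * 25, rid=f"r{i}") for i in range(200)]
        a = subsample_reads(reads, 0.1, seed=9)
        assert a == subsample_reads(reads, 0.1, seed=9)
        positions = [reads.index(r) for r in a]
        assert positions == sorted(positions)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ArgumentError):
            subsample_reads([], 0.0, seed=1)


class TestQc:
    def test_short_read_discarded(self):
        kept, n_failed = qc_reads([_read("A" * 69)])
        assert kept == [] and n_failed == 1

    def test_boundary_read_kept(self):
        # exactly 70 bp and mean quality exactly 20 both survive
        kept, n_failed = qc_reads([_read("A" * 70, quality=20)])
        assert len(kept) == 1 and n_failed == 0

    def test_low_mean_quality_discarded(self):
        quals = (19,) * 50 + (20,) * 50  # mean 19.5
        read = ReadRecord("r", "A" * 100, quals)
        kept, n_failed = qc_reads([read])
        assert kept == [] and n_failed == 1

    def test_empty_input(self):
        assert qc_reads([]) == ([], 0)


class TestPseudoMap:
    def test_exact_substring_scores_zero(self, genome, index):
        mapped, score = pseudo_map_read(_read(genome.sequence[500:600]), index)
        assert mapped and score == 0

    def test_reverse_strand_read_maps(self, genome, index):
        from sgbkit.sketching import reverse_complement

        mapped, score = pseudo_map_read(
            _read(reverse_complement(genome.sequence[500:600])), index
        )
        assert mapped and score == 0

    @pytest.mark.parametrize("n_mismatches,expect_mapped,expect_score",
                             [(3, True, -18), (4, False, -24)])
    def test_mismatch_scoring(self, genome, index, n_mismatches, expect_mapped, expect_score):
        seq = list(genome.sequence[500:600])
        for i in range(n_mismatches):
            pos = 40 + 2 * i  # clustered: keeps exact 31-mer seeds elsewhere
            seq[pos] = FLIP[seq[pos]]
        mapped, score = pseudo_map_read(_read("".join(seq)), index)
        assert mapped is expect_mapped and score == expect_score

    def test_read_shorter_than_seed_is_unmapped(self, index):
        mapped, score = pseudo_map_read(_read("ACGT" * 5), index)
        assert (mapped, score) == (False, None)

    def test_foreign_read_is_unmapped(self, index):
        foreign = generate_root_genome(1000, 0.5, seed=77)
        mapped, score = pseudo_map_read(_read(foreign.sequence[:100]), index)
        assert (mapped, score) == (False, None)


class TestHostFilter:
    def test_host_read_removed_bacterial_kept(self, genome, index):
        host = generate_root_genome(5000, 0.5, seed=55, genome_id="host")
        host_index = build_index("host", [host])
        reads = [_read(host.sequence[100:200], rid="h"),
                 _read(genome.sequence[100:200], rid="b")]
        kept, n_removed = host_filter(reads, host_index)
        assert n_removed == 1 and [r.id for r in kept] == ["b"]

    def test_empty_host_index_keeps_all(self, genome):
        reads = [_read(genome.sequence[:100])]
        kept, n_removed = host_filter(reads, build_index("host", []))
        assert kept == reads and n_removed == 0


@pytest.fixture(scope="module")
def tiers():
    g1 = generate_root_genome(10_000, 0.5, seed=31, genome_id="t1g")
    g3 = generate_root_genome(10_000, 0.5, seed=32, genome_id="t3g")
    return {
        "g1": g1,
        "g3": g3,
        "indexes": [
            build_index("reference_genomes", [g1]),
            build_index("human_sgbs", []),
            build_index("nhp_psgbs", [g3]),
        ],
    }


class TestIncrementalMap:
    def test_tier1_reads_attributed_to_tier1(self, tiers):
        reads = simulate_reads(tiers["g1"], 50, 100, 0.0, seed=1)
        mapped, unmapped = incremental_map(reads, tiers["indexes"])
        assert mapped == {"reference_genomes": 50, "human_sgbs": 0, "nhp_psgbs": 0}
        assert unmapped == 0

    def test_tier3_only_reads_fall_through(self, tiers):
        reads = simulate_reads(tiers["g3"], 50, 100, 0.0, seed=2)
        mapped, _ = incremental_map(reads, tiers["indexes"])
        assert mapped["nhp_psgbs"] == 50 and mapped["reference_genomes"] == 0

    def test_first_tier_wins_for_shared_genome(self, tiers):
        shared = [
            build_index("reference_genomes", [tiers["g3"]]),
            build_index("human_sgbs", []),
            build_index("nhp_psgbs", [tiers["g3"]]),
        ]
        reads = simulate_reads(tiers["g3"], 30, 100, 0.0, seed=3)
        mapped, _ = incremental_map(reads, shared)
        assert mapped == {"reference_genomes": 30, "human_sgbs": 0, "nhp_psgbs": 0}

    def test_duplicate_tier_names_rejected(self, tiers):
        dup = [tiers["indexes"][0], tiers["indexes"][0]]
        with pytest.raises(ArgumentError):
            incremental_map([], dup)

    def test_permuting_tiers_preserves_total_mapped(self, tiers):
        reads = (
            simulate_reads(tiers["g1"], 40, 100, 0.0, seed=4)
            + simulate_reads(tiers["g3"], 40, 100, 0.0, seed=5)
        )
        forward, un_f = incremental_map(reads, tiers["indexes"])
        backward, un_b = incremental_map(reads, tiers["indexes"][::-1])
        assert sum(forward.values()) == sum(backward.values())
        assert un_f == un_b


class TestReportAndGain:
    def test_conservation_invariant(self, genome, index):
        rng = np.random.default_rng(12)
        reads = simulate_reads(genome, 300, 100, 0.01, seed=6)
        # sprinkle in junk reads that fail QC or never map
        reads += [ReadRecord(f"short{i}", "ACGT" * 10, (30,) * 40) for i in range(20)]
        reads += [
            ReadRecord(
                f"rand{i}",
                "".join(rng.choice(list("ACGT"), 100)),
                (30,) * 100,
            )
            for i in range(30)
        ]
        report = run_mappability(
            "s1", reads, [index], fraction=0.5, seed=7
        )
        assert report.n_subsampled == 175
        assert (
            report.n_subsampled
            == report.n_host_removed + report.n_qc_failed + report.n_hq
        )
        assert sum(report.mapped_per_tier.values()) + report.n_unmapped == report.n_hq
        cumulative = list(report.fraction_cumulative.values())
        assert cumulative == sorted(cumulative)

    def test_lowering_min_score_never_decreases_mappability(self, genome, index):
        reads = simulate_reads(genome, 200, 100, 0.02, seed=8)
        fractions = [
            run_mappability("s", reads, [index], fraction=1.0, seed=0, min_score=ms).fraction_overall
            for ms in (0, -12, -20, -40)
        ]
        assert fractions == sorted(fractions)

    @pytest.mark.parametrize(
        "before,after,expected",
        [(0.05, 0.356, 612.0), (0.2, 0.2, 0.0), (0.1, 0.05, -50.0)],
    )
    def test_gain_arithmetic(self, before, after, expected):
        assert mappability_gain(before, after) == pytest.approx(expected)

    def test_zero_baseline_gain_is_undefined(self):
        with pytest.raises(UndefinedGainError):
            mappability_gain(0.0, 0.3)
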