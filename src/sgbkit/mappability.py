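"""Tiered incremental read-mappability estimation.

The procedure mirrors how catalog growth is evaluated in large MAG studies:
subsample the raw reads of a metagenome (default 1%), remove host-derived
reads, discard short (< 70 bp) or low-quality (mean Phred < 20) reads, then
map the surviving high-quality reads against an ordered series of genome
catalogs ("tiers") — public reference genomes first, then human-derived
genome bins, then the newly reconstructed primate-specific bins.  Mapping
is incremental: a read is attributed to the first tier it maps to and is
never offered to later tiers.  The mappability fraction of a sample is the
number of mapped reads over the number of high-quality reads.

Reads are placed with a deterministic seed-and-extend pseudo-mapper:
exact 31-mer seeds locate candidate ungapped end-to-end placements on
either strand; a placement scores 0 per match and -6 per mismatch, and a
read counts as mapped when its best score is at least ``min_score``
(default -20, i.e. at most 3 mismatches).  The mapper has no gaps — the
synthetic reads it is designed for carry substitution errors only — and
sits behind a small interface so an external aligner could be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ArgumentError, UndefinedGainError
from .io_formats import ReadRecord, SequenceRecord
from .sketching import forward_kmer_codes, reverse_complement

TIER_ORDER = ("reference_genomes", "human_sgbs", "nhp_psgbs")
DEFAULT_SEED_K = 31
DEFAULT_MIN_SCORE = -20
MISMATCH_PENALTY = -6


@dataclass
class TierIndex:
    """Exact-seed k-mer index over one catalog of genomes."""

    tier_name: str
    seed_k: int
    genome_ids: list[str] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)
    index: dict[int, list[tuple[str, int]]] = field(default_factory=dict)

    def add_genome(self, record: SequenceRecord) -> None:
        self.genome_ids.append(record.id)
        self.sequences[record.id] = record.sequence
        codes, positions = forward_kmer_codes(record.sequence, self.seed_k)
        for code, pos in zip(codes.tolist(), positions.tolist()):
            self.index.setdefault(code, []).append((record.id, int(pos)))


def build_index(
    tier_name: str,
    genomes: Sequence[SequenceRecord],
    seed_k: int = DEFAULT_SEED_K,
) -> TierIndex:
    idx = TierIndex(tier_name=tier_name, seed_k=seed_k)
    for rec in genomes:
        idx.add_genome(rec)
    return idx


@dataclass(frozen=True)
class MappabilityReport:
    """Per-tier read accounting for one sample."""

    sample_id: str
    n_raw: int
    n_subsampled: int
    n_host_removed: int
    n_qc_failed: int
    n_hq: int
    mapped_per_tier: dict[str, int]
    n_unmapped: int
    subsample_seed: int | None = None

    def __post_init__(self) -> None:
        if sum(self.mapped_per_tier.values()) + self.n_unmapped != self.n_hq:
            raise ArgumentError(
                "mapped counts plus unmapped must equal high-quality reads"
            )

    @property
    def fraction_overall(self) -> float:
        if self.n_hq == 0:
            return math.nan
        return sum(self.mapped_per_tier.values()) / self.n_hq

    @property
    def fraction_per_tier(self) -> dict[str, float]:
        if self.n_hq == 0:
            return {t: math.nan for t in self.mapped_per_tier}
        return {t: c / self.n_hq for t, c in self.mapped_per_tier.items()}

    @property
    def fraction_cumulative(self) -> dict[str, float]:
        out: dict[str, float] = {}
        running = 0
        for tier, count in self.mapped_per_tier.items():
            running += count
            out[tier] = running / self.n_hq if self.n_hq else math.nan
        return out

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_raw": self.n_raw,
            "n_subsampled": self.n_subsampled,
            "n_host_removed": self.n_host_removed,
            "n_qc_failed": self.n_qc_failed,
            "n_hq": self.n_hq,
            "mapped_per_tier": dict(self.mapped_per_tier),
            "n_unmapped": self.n_unmapped,
            "fraction_overall": self.fraction_overall,
            "fraction_per_tier": self.fraction_per_tier,
            "fraction_cumulative": self.fraction_cumulative,
            "subsample_seed": self.subsample_seed,
        }


def subsample_reads(
    reads: Sequence[ReadRecord], fraction: float, seed: int
) -> list[ReadRecord]:
    """Draw floor(fraction * n) reads uniformly without replacement.

    Output preserves the original read order; deterministic given ``seed``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ArgumentError(f"subsample fraction {fraction} outside (0, 1]")
    n = len(reads)
    # round to 9 decimals first so e.g. 0.29 * 100 == 28.999... still floors to 29
    m = math.floor(round(fraction * n, 9))
    if m == n:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=m, replace=False))
    return [reads[i] for i in keep]


def qc_reads(reads: Sequence[ReadRecord]) -> tuple[list[ReadRecord], int]:
    """Drop reads shorter than 70 bp or with mean Phred quality below 20."""
    kept = [
        r for r in reads if len(r.sequence) >= 70 and r.mean_quality >= 20.0
    ]
    return kept, len(reads) - len(kept)


def _candidate_placements(
    query: str, index: TierIndex
) -> set[tuple[str, int]]:
    codes, offsets = forward_kmer_codes(query, index.seed_k)
    candidates: set[tuple[str, int]] = set()
    length = len(query)
    for code, offset in zip(codes.tolist(), offsets.tolist()):
        for gid, pos in index.index.get(code, ()):
            start = pos - offset
            if start >= 0 and start + length <= len(index.sequences[gid]):
                candidates.add((gid, start))
    return candidates


def _hamming(a: str, b: str) -> int:
    xa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return int(np.count_nonzero(xa != xb))


def pseudo_map_read(
    read: ReadRecord, index: TierIndex, min_score: int = DEFAULT_MIN_SCORE
) -> tuple[bool, int | None]:
    """Best ungapped end-to-end placement of a read on either strand.

    Returns ``(mapped, best_score)``; a read shorter than the seed length
    is unmapped (score ``None``), not an error.
    """
    if len(read.sequence) < index.seed_k:
        return False, None
    best: int | None = None
    for query in (read.sequence, reverse_complement(read.sequence)):
        for gid, start in _candidate_placements(query, index):
            window = index.sequences[gid][start : start + len(query)]
            score = MISMATCH_PENALTY * _hamming(query, window)
            if best is None or score > best:
                best = score
                if best == 0:
                    break
        if best == 0:
            break
    if best is None:
        return False, None
    return best >= min_score, best


def host_filter(
    reads: Sequence[ReadRecord],
    host_index: TierIndex | None,
    min_score: int = DEFAULT_MIN_SCORE,
) -> tuple[list[ReadRecord], int]:
    """Remove reads that map to the host genome index."""
    if host_index is None or not host_index.genome_ids:
        return list(reads), 0
    kept = [r for r in reads if not pseudo_map_read(r, host_index, min_score)[0]]
    return kept, len(reads) - len(kept)


def incremental_map(
    reads: Sequence[ReadRecord],
    tiers: Sequence[TierIndex],
    min_score: int = DEFAULT_MIN_SCORE,
) -> tuple[dict[str, int], int]:
    """Attribute each read to the FIRST tier it maps to.

    Later tiers only see reads unmapped so far, so a genome present in two
    tiers contributes all its reads to the earlier one.
    """
    names = [t.tier_name for t in tiers]
    if len(set(names)) != len(names):
        raise ArgumentError(f"duplicate tier names: {names}")
    mapped: dict[str, int] = {name: 0 for name in names}
    remaining = list(reads)
    for tier in tiers:
        still_unmapped = []
        for read in remaining:
            if pseudo_map_read(read, tier, min_score)[0]:
                mapped[tier.tier_name] += 1
            else:
                still_unmapped.append(read)
        remaining = still_unmapped
    return mapped, len(remaining)


def run_mappability(
    sample_id: str,
    reads: Sequence[ReadRecord],
    tiers: Sequence[TierIndex],
    *,
    host_index: TierIndex | None = None,
    fraction: float = 0.01,
    seed: int = 0,
    min_score: int = DEFAULT_MIN_SCORE,
) -> MappabilityReport:
    """Full per-sample pipeline: subsample, host-filter, QC, tiered mapping."""
    sub = subsample_reads(reads, fraction, seed)
    hostfree, n_host = host_filter(sub, host_index, min_score)
    hq, n_failed = qc_reads(hostfree)
    mapped, n_unmapped = incremental_map(hq, tiers, min_score)
    return MappabilityReport(
        sample_id=sample_id,
        n_raw=len(reads),
        n_subsampled=len(sub),
        n_host_removed=n_host,
        n_qc_failed=n_failed,
        n_hq=len(hq),
        mapped_per_tier=mapped,
        n_unmapped=n_unmapped,
        subsample_seed=seed,
    )


def mappability_gain(fraction_before: float, fraction_after: float) -> float:
    """Percent change in mappability relative to the baseline fraction."""
    if fraction_before == 0.0:
        raise UndefinedGainError(
            "gain is infinite: baseline mappability fraction is zero"
        )
    return 100.0 * (fraction_after - fraction_before) / fraction_before
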