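"""Synthetic genomes, MAGs, reads, and cohorts with known ground truth.

The generator emulates the statistical structure the pipeline operates on:

* a star phylogeny of bacterial species — species genomes evolve from a
  shared root ancestor at half the configured inter-cluster divergence, and
  MAG genomes evolve from their species genome at half the intra-cluster
  divergence, so planted PAIRWISE divergences equal the configured values
  (these are what the 5%/15%/30% clustering thresholds act on);
* MAGs with controlled completeness (non-overlapping contig windows
  covering a chosen fraction of the genome) and contamination (foreign
  contigs from other species contributing a chosen fraction of assembled
  length);
* shotgun reads with uniform start positions, random strand, substitution
  errors, and a two-level quality string (Phred 30 for correct bases, 15
  at error positions) so the mean-quality filter is exercisable;
* cohorts of samples in labeled groups with planted per-group species
  prevalence, for prevalence-enrichment testing.

Evolution is substitution-only with an exact site count (round(d * L)
positions changed), so planted divergence equals the Hamming fraction with
no sampling noise.  Everything is deterministic given the scenario seed:
per-operation seeds are derived from it by stable labeled hashing.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ArgumentError
from .io_formats import (
    MagCatalogEntry,
    ReadRecord,
    SampleMetadata,
    SequenceRecord,
    write_catalog,
    write_fasta,
    write_fastq,
    write_sample_metadata,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MIN_GENOME_LENGTH = 1000


def derive_seed(seed: int, label: str) -> int:
    """Stable sub-seed for one labeled operation; always below 2**31."""
    return (zlib.crc32(label.encode()) ^ (seed & 0x7FFFFFFF)) % (2**31)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic cohort."""

    n_species: int = 5
    genome_length: int = 50_000
    gc_content: float = 0.5
    intra_divergence: float = 0.02  # max pairwise divergence within a species
    inter_divergence: float = 0.10  # pairwise divergence between species
    mags_per_species: tuple[int, int] = (4, 4)
    completeness_range: tuple[float, float] = (80.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 3.0)
    n_contigs: int = 10
    read_length: int = 100
    reads_per_sample: int = 0
    error_rate: float = 0.0
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"group_a": 20, "group_b": 20}
    )
    host_category_of_group: Mapping[str, str] = field(
        default_factory=lambda: {"group_a": "nhp_wild", "group_b": "nhp_wild"}
    )
    base_prevalence: float = 0.5
    planted_enrichment: tuple[tuple[int, Mapping[str, float]], ...] = ()
    species_with_reference: tuple[int, ...] = ()
    species_with_human: tuple[int, ...] = ()
    seed: int = 42

    def __post_init__(self) -> None:
        if self.intra_divergence >= self.inter_divergence:
            raise ArgumentError(
                "intra-species divergence must be below inter-species divergence"
            )
        for frac in (self.intra_divergence, self.inter_divergence, self.error_rate):
            if not 0.0 <= frac <= 1.0:
                raise ArgumentError(f"fraction {frac} outside [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure matching the emitted files."""

    species_of_mag: dict[str, int]
    true_divergence: list[list[float]]  # species x species pairwise
    true_completeness: dict[str, float]
    true_contamination: dict[str, float]
    true_presence: dict[str, dict[str, int]]  # species label -> sample -> 0/1
    tier_of_genome: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        doc["species_of_mag"] = {k: int(v) for k, v in doc["species_of_mag"].items()}
        return cls(**doc)


def generate_root_genome(
    length: int, gc: float = 0.5, seed: int = 0, genome_id: str = "root"
) -> SequenceRecord:
    """Random i.i.d. genome with the requested GC content."""
    if length < MIN_GENOME_LENGTH:
        raise ArgumentError(f"genome length {length} below floor {MIN_GENOME_LENGTH}")
    if not 0.0 < gc < 1.0:
        raise ArgumentError(f"gc content {gc} must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = rng.choice(_BASES, size=length, p=probs)
    return SequenceRecord(id=genome_id, sequence=bases.tobytes().decode("ascii"))


def evolve_genome(
    parent: SequenceRecord,
    divergence: float,
    seed: int,
    genome_id: str | None = None,
) -> SequenceRecord:
    """Substitute exactly round(divergence * L) positions to different bases."""
    if not 0.0 <= divergence < 0.5:
        raise ArgumentError(f"divergence {divergence} outside [0, 0.5)")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(parent.sequence.encode("ascii"), dtype=np.uint8).copy()
    n_sub = int(round(divergence * len(arr)))
    if n_sub:
        sites = rng.choice(len(arr), size=n_sub, replace=False)
        # shift each chosen base by 1-3 positions in base space: always a change
        code = np.searchsorted(_BASES, arr[sites])
        shift = rng.integers(1, 4, size=n_sub)
        arr[sites] = _BASES[(code + shift) % 4]
    return SequenceRecord(
        id=genome_id or f"{parent.id}_mut", sequence=arr.tobytes().decode("ascii")
    )


def fragment_to_mag(
    genome: SequenceRecord,
    completeness: float,
    contaminants: Sequence[SequenceRecord],
    contamination: float,
    n_contigs: int,
    seed: int,
    *,
    mag_id: str | None = None,
) -> list[SequenceRecord]:
    """Fragment a genome into a MAG with planted completeness/contamination.

    Native contigs are non-overlapping windows (one per equal block of the
    genome) totalling ``completeness``% of its length; contaminant contigs
    from foreign species contribute ``contamination``% of the assembled
    length.  Returns the contig records; quality metadata is the caller's
    to record.
    """
    if not 0.0 < completeness <= 100.0:
        raise ArgumentError(f"completeness {completeness} outside (0, 100]")
    if not 0.0 <= contamination < 100.0:
        raise ArgumentError(f"contamination {contamination} outside [0, 100)")
    if contamination > 0 and not contaminants:
        raise ArgumentError("contamination requested but no contaminant genomes given")
    rng = np.random.default_rng(seed)
    mid = mag_id or f"{genome.id}_mag"
    length = len(genome.sequence)

    if completeness == 100.0 and contamination == 0.0 and n_contigs == 1:
        return [SequenceRecord(id=f"{mid}_c1", sequence=genome.sequence)]

    target_native = int(round(completeness / 100.0 * length))
    n_contigs = max(1, min(n_contigs, target_native))
    block = length // n_contigs
    per_contig = target_native // n_contigs
    remainder = target_native - per_contig * n_contigs
    contigs: list[SequenceRecord] = []
    for i in range(n_contigs):
        want = per_contig + (1 if i < remainder else 0)
        want = min(want, block)
        start = i * block + int(rng.integers(0, block - want + 1))
        contigs.append(
            SequenceRecord(
                id=f"{mid}_c{i + 1}",
                sequence=genome.sequence[start : start + want],
            )
        )

    if contamination > 0:
        native_len = sum(len(c.sequence) for c in contigs)
        foreign_len = int(round(contamination / (100.0 - contamination) * native_len))
        j = 0
        while foreign_len > 0:
            donor = contaminants[int(rng.integers(0, len(contaminants)))]
            take = min(foreign_len, max(500, foreign_len // 2), len(donor.sequence))
            start = int(rng.integers(0, len(donor.sequence) - take + 1))
            j += 1
            contigs.append(
                SequenceRecord(
                    id=f"{mid}_x{j}",
                    sequence=donor.sequence[start : start + take],
                )
            )
            foreign_len -= take
    return contigs


def simulate_reads(
    genome: SequenceRecord,
    n: int,
    read_length: int,
    error_rate: float,
    seed: int,
    *,
    id_prefix: str | None = None,
) -> list[ReadRecord]:
    """Uniform shotgun reads with substitution errors and two-level qualities."""
    if n <= 0:
        raise ArgumentError(f"read count must be positive, got {n}")
    if read_length > len(genome.sequence):
        raise ArgumentError("read length exceeds genome length")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or genome.id
    starts = rng.integers(0, len(genome.sequence) - read_length + 1, size=n)
    strands = rng.integers(0, 2, size=n)
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGT", b"TGCA"):
        comp[x] = y
    reads: list[ReadRecord] = []
    for i in range(n):
        window = arr[starts[i] : starts[i] + read_length].copy()
        if strands[i]:
            window = comp[window[::-1]]
        errors = rng.random(read_length) < error_rate
        if errors.any():
            sites = np.nonzero(errors)[0]
            code = np.searchsorted(_BASES, window[sites])
            shift = rng.integers(1, 4, size=sites.size)
            window[sites] = _BASES[(code + shift) % 4]
        quals = np.where(errors, 15, 30)
        reads.append(
            ReadRecord(
                id=f"{prefix}_r{i}",
                sequence=window.tobytes().decode("ascii"),
                qualities=tuple(int(q) for q in quals),
            )
        )
    return reads


def _planted_prevalence(cfg: ScenarioConfig, species: int, group: str) -> float:
    for sp, prevalences in cfg.planted_enrichment:
        if sp == species and group in prevalences:
            return float(prevalences[group])
    return cfg.base_prevalence


def generate_cohort(cfg: ScenarioConfig, out_dir: str | Path) -> GroundTruth:
    """Emit a full synthetic cohort to ``out_dir`` and return its ground truth.

    Writes species genomes (``genomes/``), MAG FASTAs (``mags/``), a MAG
    catalog TSV, sample metadata TSV, per-sample FASTQ files (when
    ``reads_per_sample > 0``), tier file lists, and the ground-truth JSON.
    Byte-identical across reruns with the same config.
    """
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "mags").mkdir(exist_ok=True)
    (out / "tiers").mkdir(exist_ok=True)

    root = generate_root_genome(
        cfg.genome_length, cfg.gc_content, derive_seed(cfg.seed, "root"), "root"
    )
    species_genomes = [
        evolve_genome(
            root,
            cfg.inter_divergence / 2.0,
            derive_seed(cfg.seed, f"species:{i}"),
            genome_id=f"species_{i:02d}",
        )
        for i in range(cfg.n_species)
    ]
    for rec in species_genomes:
        write_fasta(out / "genomes" / f"{rec.id}.fasta", [rec])

    # samples and planted presence
    samples: list[SampleMetadata] = []
    for group in sorted(cfg.n_samples_per_group):
        for j in range(cfg.n_samples_per_group[group]):
            samples.append(
                SampleMetadata(
                    sample_id=f"{group}_s{j:03d}",
                    dataset=f"synthetic_{group}",
                    group_label=group,
                    n_raw_reads=cfg.reads_per_sample,
                )
            )
    presence_rng = np.random.default_rng(derive_seed(cfg.seed, "presence"))
    presence: dict[str, dict[str, int]] = {}
    for i in range(cfg.n_species):
        row = {}
        for s in samples:
            p = _planted_prevalence(cfg, i, s.group_label)
            row[s.sample_id] = int(presence_rng.random() < p)
        presence[f"species_{i:02d}"] = row

    # MAGs: per species, drawn from samples where the species occurs
    mag_rng = np.random.default_rng(derive_seed(cfg.seed, "mags"))
    entries: list[MagCatalogEntry] = []
    species_of_mag: dict[str, int] = {}
    true_comp: dict[str, float] = {}
    true_cont: dict[str, float] = {}
    lo, hi = cfg.mags_per_species
    for i, sp_genome in enumerate(species_genomes):
        n_mags = int(mag_rng.integers(lo, hi + 1))
        present = [s for s in samples if presence[sp_genome.id][s.sample_id]]
        chosen: list[SampleMetadata] = []
        if present:
            take = min(n_mags, len(present))
            idx = mag_rng.choice(len(present), size=take, replace=False)
            chosen = [present[j] for j in sorted(idx)]
        missing = n_mags - len(chosen)
        if missing > 0:
            absent = [s for s in samples if not presence[sp_genome.id][s.sample_id]]
            idx = mag_rng.choice(len(absent), size=missing, replace=False)
            for j in sorted(idx):
                chosen.append(absent[j])
                presence[sp_genome.id][absent[j].sample_id] = 1
        contaminants = [g for g in species_genomes if g.id != sp_genome.id]
        for m, sample in enumerate(chosen):
            mag_id = f"mag_sp{i:02d}_{m:02d}"
            completeness = float(
                mag_rng.uniform(cfg.completeness_range[0], cfg.completeness_range[1])
            )
            contamination = float(
                mag_rng.uniform(cfg.contamination_range[0], cfg.contamination_range[1])
            )
            mag_genome = evolve_genome(
                sp_genome,
                cfg.intra_divergence / 2.0,
                derive_seed(cfg.seed, f"mag-genome:{mag_id}"),
                genome_id=mag_id,
            )
            contigs = fragment_to_mag(
                mag_genome,
                completeness,
                contaminants,
                contamination,
                cfg.n_contigs,
                derive_seed(cfg.seed, f"mag-frag:{mag_id}"),
                mag_id=mag_id,
            )
            fasta_path = out / "mags" / f"{mag_id}.fasta"
            write_fasta(fasta_path, contigs)
            entries.append(
                MagCatalogEntry(
                    mag_id=mag_id,
                    fasta_path=str(fasta_path),
                    dataset=sample.dataset,
                    sample_id=sample.sample_id,
                    host_species="synthetic_host",
                    host_category=cfg.host_category_of_group.get(
                        sample.group_label, "nhp_wild"
                    ),
                    country="synthetic",
                    completeness=completeness,
                    contamination=contamination,
                )
            )
            species_of_mag[mag_id] = i
            true_comp[mag_id] = completeness
            true_cont[mag_id] = contamination

    # optional reference genomes and human-derived MAGs (novelty-class ladder)
    for i in cfg.species_with_reference:
        ref_id = f"ref_sp{i:02d}"
        rec = SequenceRecord(id=ref_id, sequence=species_genomes[i].sequence)
        path = out / "genomes" / f"{ref_id}.fasta"
        write_fasta(path, [rec])
        entries.append(
            MagCatalogEntry(
                mag_id=ref_id,
                fasta_path=str(path),
                dataset="reference_db",
                sample_id="none",
                host_species="none",
                host_category="reference",
                country="none",
                completeness=100.0,
                contamination=0.0,
            )
        )
    for i in cfg.species_with_human:
        hum_id = f"human_sp{i:02d}"
        genome = evolve_genome(
            species_genomes[i],
            cfg.intra_divergence / 2.0,
            derive_seed(cfg.seed, f"human:{i}"),
            genome_id=hum_id,
        )
        path = out / "mags" / f"{hum_id}.fasta"
        write_fasta(path, [genome])
        entries.append(
            MagCatalogEntry(
                mag_id=hum_id,
                fasta_path=str(path),
                dataset="human_db",
                sample_id="human_sample",
                host_species="Homo sapiens",
                host_category="human_nonwesternized",
                country="none",
                completeness=100.0,
                contamination=0.0,
            )
        )

    # reads per sample, drawn evenly from the species present in the sample
    if cfg.reads_per_sample > 0:
        (out / "reads").mkdir(exist_ok=True)
        for s in samples:
            present_sp = [
                g for g in species_genomes if presence[g.id][s.sample_id]
            ]
            if not present_sp:
                continue
            per_sp = cfg.reads_per_sample // len(present_sp)
            reads: list[ReadRecord] = []
            for g in present_sp:
                if per_sp <= 0:
                    continue
                reads.extend(
                    simulate_reads(
                        g,
                        per_sp,
                        cfg.read_length,
                        cfg.error_rate,
                        derive_seed(cfg.seed, f"reads:{s.sample_id}:{g.id}"),
                        id_prefix=f"{s.sample_id}_{g.id}",
                    )
                )
            write_fastq(out / "reads" / f"{s.sample_id}.fastq", reads)

    # tier membership: referenced species -> tier 1; human-only -> tier 2;
    # primate-only -> tier 3
    tier_of_genome: dict[str, str] = {}
    for i, g in enumerate(species_genomes):
        if i in cfg.species_with_reference:
            tier_of_genome[g.id] = "reference_genomes"
        elif i in cfg.species_with_human:
            tier_of_genome[g.id] = "human_sgbs"
        else:
            tier_of_genome[g.id] = "nhp_psgbs"
    for tier in ("reference_genomes", "human_sgbs", "nhp_psgbs"):
        members = [g for g, t in tier_of_genome.items() if t == tier]
        # relative to the cohort directory, so reruns are byte-identical
        (out / "tiers" / f"{tier}.txt").write_text(
            "".join(f"genomes/{g}.fasta\n" for g in members)
        )

    write_catalog(out / "catalog.tsv", entries)
    write_sample_metadata(out / "samples.tsv", samples)

    # planted pairwise species divergence: 0 on the diagonal, inter elsewhere
    truth = GroundTruth(
        species_of_mag=species_of_mag,
        true_divergence=[
            [0.0 if i == j else cfg.inter_divergence for j in range(cfg.n_species)]
            for i in range(cfg.n_species)
        ],
        true_completeness=true_comp,
        true_contamination=true_cont,
        true_presence=presence,
        tier_of_genome=tier_of_genome,
    )
    truth.to_json(out / "ground_truth.json")
    return truth


def simulate_presence_cohort(
    n_null_features: int,
    n_samples_per_group: Mapping[str, int],
    base_prevalence: float,
    planted: Sequence[tuple[str, Mapping[str, float]]],
    seed: int,
) -> "PresenceMatrix":
    """Binary feature-by-sample cohort for prevalence-enrichment studies.

    Null features are Bernoulli(base_prevalence) in every group; each
    planted feature has its own per-group prevalence.  Returns a
    :class:`~sgbkit.enrichment.PresenceMatrix` ready for
    :func:`~sgbkit.enrichment.enrichment_scan`.
    """
    from .enrichment import PresenceMatrix

    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    for group in sorted(n_samples_per_group):
        for j in range(n_samples_per_group[group]):
            sid = f"{group}_s{j:04d}"
            sample_ids.append(sid)
            group_of[sid] = group
    groups = np.array([group_of[s] for s in sample_ids])

    feature_ids: list[str] = []
    rows: list[np.ndarray] = []
    for name, prevalences in planted:
        p = np.array([prevalences.get(g, base_prevalence) for g in groups])
        rows.append((rng.random(len(sample_ids)) < p).astype(int))
        feature_ids.append(name)
    for i in range(n_null_features):
        rows.append((rng.random(len(sample_ids)) < base_prevalence).astype(int))
        feature_ids.append(f"null_{i:04d}")
    return PresenceMatrix(
        feature_ids=tuple(feature_ids),
        sample_ids=tuple(sample_ids),
        presence=np.array(rows, dtype=int),
        group_of=group_of,
    )
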