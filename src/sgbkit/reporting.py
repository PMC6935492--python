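"""Pipeline orchestration and summary tables.

Produces the dataset-level accounting tables a MAG-catalog study reports:
per-dataset counts and percentages of MAGs by novelty class of their SGB
(with a Total row), quality-tier counts with the high-quality fraction
among genomes of medium quality or better, and an end-to-end driver that
runs sketching, clustering, classification, taxonomy, and quality
summaries over a MAG catalog and writes every table with a config-hash
header for provenance.

Percentages are rounded half-away-from-zero to one decimal (two in
verbose mode); raw fractions are always emitted alongside.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import binning, sketching, taxonomy
from .errors import ArgumentError, ConsistencyError
from .io_formats import MagCatalogEntry, read_catalog, read_fasta

NOVELTY_ORDER = ("kSGB", "uSGB", "pSGB")


@dataclass(frozen=True)
class PipelineConfig:
    """All fixed constants of one pipeline run, serialized with every output."""

    k: int = sketching.DEFAULT_K
    s: int = sketching.DEFAULT_SKETCH_SIZE
    hash_seed: int = sketching.DEFAULT_HASH_SEED
    sgb_threshold: float = 0.05
    ggb_threshold: float = 0.15
    fgb_threshold: float = 0.30
    quality_medium_completeness: float = 50.0
    quality_high_completeness: float = 90.0
    quality_max_contamination: float = 5.0
    mappability_fraction: float = 0.01
    mappability_min_score: int = -20
    subsample_seed: int = 0
    enrichment_alpha: float = 0.05
    enrichment_method: str = "bonferroni"
    percent_decimals: int = 1

    def __post_init__(self) -> None:
        if not self.sgb_threshold < self.ggb_threshold < self.fgb_threshold:
            raise ArgumentError("bin thresholds must be strictly increasing")

    def to_text(self) -> str:
        lines = ["[pipeline]"]
        for key, value in asdict(self).items():
            lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Round 100*fraction half-away-from-zero to the printed precision."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def classification_table_from_counts(
    counts: Mapping[str, tuple[int, int, int]], decimals: int = 1
) -> pd.DataFrame:
    """Per-dataset MAG counts by novelty class, with percentages and a Total.

    ``counts`` maps dataset -> (n_kSGB, n_uSGB, n_pSGB) MAG counts.
    Percentages are computed within each row's own MAG total.
    """
    rows = []
    totals = [0, 0, 0]
    for dataset in sorted(counts):
        k, u, p = counts[dataset]
        totals = [totals[0] + k, totals[1] + u, totals[2] + p]
        rows.append((dataset, k, u, p))
    rows.append(("Total", *totals))
    table = []
    for dataset, k, u, p in rows:
        n = k + u + p
        if n == 0:
            raise ArgumentError(f"dataset {dataset!r} has no MAGs")
        table.append(
            {
                "dataset": dataset,
                "n_mags": n,
                "n_kSGB": k,
                "pct_kSGB": round_percent(k / n, decimals),
                "n_uSGB": u,
                "pct_uSGB": round_percent(u / n, decimals),
                "n_pSGB": p,
                "pct_pSGB": round_percent(p / n, decimals),
                "frac_kSGB": k / n,
                "frac_uSGB": u / n,
                "frac_pSGB": p / n,
            }
        )
    return pd.DataFrame(table)


def classification_table(
    sgb_of_mag: Mapping[str, str],
    catalog: binning.BinCatalog,
    mags: Sequence[MagCatalogEntry],
    decimals: int = 1,
) -> pd.DataFrame:
    """Classification table from actual SGB membership of a MAG set."""
    novelty = {b.bin_id: b.novelty_class for b in catalog.at_level("SGB")}
    counts: dict[str, list[int]] = {}
    for mag in mags:
        if mag.mag_id not in sgb_of_mag:
            raise ConsistencyError(f"MAG {mag.mag_id!r} has no SGB assignment")
        cls = novelty[sgb_of_mag[mag.mag_id]]
        row = counts.setdefault(mag.dataset, [0, 0, 0])
        row[NOVELTY_ORDER.index(cls)] += 1
    return classification_table_from_counts(
        {ds: tuple(v) for ds, v in counts.items()}, decimals
    )


def quality_summary(mags: Sequence[MagCatalogEntry]) -> dict:
    """Tier counts plus the high-quality fraction among medium-or-better."""
    tiers = [taxonomy.quality_tier(m.completeness, m.contamination) for m in mags]
    n_high = tiers.count("high")
    n_medium = tiers.count("medium")
    n_fail = tiers.count("fail")
    passing = n_high + n_medium
    return {
        "n_high": n_high,
        "n_medium": n_medium,
        "n_fail": n_fail,
        "n_passing": passing,
        "pct_high_of_passing": round_percent(n_high / passing) if passing else None,
        "frac_high_of_passing": n_high / passing if passing else None,
    }


def _log(message: str) -> None:
    print(f"[sgbkit {time.strftime('%H:%M:%S')}] {message}", file=sys.stderr)


def _write_with_header(path: Path, config: PipelineConfig, body: str) -> None:
    path.write_text(f"# sgbkit config_hash={config.config_hash()}\n{body}")


def run_pipeline(
    config: PipelineConfig,
    catalog_path: str | Path,
    out_dir: str | Path,
    *,
    reference_labels_path: str | Path | None = None,
) -> Path:
    """Sketch, cluster, classify, and summarize a MAG catalog end to end.

    Reads every genome listed in the catalog TSV, builds the three-level
    bin hierarchy, classifies SGB novelty, propagates taxonomy when
    reference labels are given, and writes all tables (with config-hash
    headers) plus the effective configuration to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = read_catalog(catalog_path)
    if not entries:
        raise ArgumentError("no genomes to sketch: catalog is empty")

    _log(f"sketching {len(entries)} genomes (k={config.k}, s={config.s})")
    sketches = [
        sketching.build_sketch(
            read_fasta(e.fasta_path),
            genome_id=e.mag_id,
            k=config.k,
            s=config.s,
            hash_seed=config.hash_seed,
        )
        for e in entries
    ]
    _log("computing pairwise distances")
    dm = sketching.pairwise_distances(sketches)
    dm.to_tsv(out / "distances.tsv")

    _log(f"clustering at {config.sgb_threshold}/{config.ggb_threshold}/{config.fgb_threshold}")
    sources = {e.mag_id: e.host_category for e in entries}
    sgbs = binning.make_sgbs(dm, sources, config.sgb_threshold)
    catalog = binning.build_hierarchy(
        sgbs, dm, sources, config.ggb_threshold, config.fgb_threshold
    )
    binning.catalog_to_tsv(catalog, out / "bins.tsv")
    if len(dm.ids) >= 2:
        (out / "dendrogram.nwk").write_text(binning.upgma_newick(dm) + "\n")

    mags = [e for e in entries if e.host_category != "reference"]
    sgb_of = catalog.sgb_of_genome()
    table = classification_table(sgb_of, catalog, mags, config.percent_decimals)
    _write_with_header(
        out / "classification_table.tsv", config, table.to_csv(sep="\t", index=False)
    )
    _log(
        "classification: "
        + ", ".join(
            f"{int(table.iloc[-1][f'n_{c}'])} {c}" for c in NOVELTY_ORDER
        )
    )

    quality = quality_summary(mags)
    _write_with_header(
        out / "quality_summary.json",
        config,
        json.dumps(quality, indent=1) + "\n",
    )

    if reference_labels_path is not None:
        labels = taxonomy.read_reference_labels(reference_labels_path)
        bin_labels = taxonomy.propagate_taxonomy(catalog, labels)
        summary = taxonomy.assignment_level_summary(catalog, bin_labels, mags)
        _write_with_header(
            out / "assignment_levels.tsv",
            config,
            summary.to_csv(sep="\t", index=False),
        )

    (out / "pipeline_config.txt").write_text(config.to_text())
    _log(f"done -> {out}")
    return out
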