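"""Quality tiers and taxonomy propagation across bin levels.

Quality tiers follow the MIMAG-style thresholds used for MAG curation:
medium quality requires completeness > 50% and contamination < 5%; high
quality requires completeness > 90% and contamination < 5%.  Both
inequalities are strict.

Taxonomy flows downhill from reference genomes: an SGB containing
references (kSGB) takes the majority label of those references down to the
species rank.  SGBs without references inherit what they can from their
genus- and family-level bins — the majority genus of the kSGBs sharing
their GGB, or the majority family of the kSGBs sharing their FGB — and stay
UNASSIGNED below that.  Ties abstain (UNASSIGNED at the tied rank and
below), so a label is only ever propagated when the references agree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .binning import BinCatalog, GenomeBin
from .errors import ArgumentError, ConsistencyError
from .io_formats import MagCatalogEntry

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "UNASSIGNED"

SUMMARY_CATEGORIES = (
    "species_known",
    "species_unknown_uSGB",
    "genus_level",
    "family_level",
    "unassigned",
)


@dataclass(frozen=True)
class TaxonLabel:
    """Seven-rank taxonomic label; UNASSIGNED propagates downward."""

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ArgumentError(f"expected {len(RANKS)} ranks, got {len(self.ranks)}")
        seen_unassigned = False
        for name, value in zip(RANKS, self.ranks):
            if value == UNASSIGNED:
                seen_unassigned = True
            elif seen_unassigned:
                raise ArgumentError(
                    f"rank {name!r} is assigned below an UNASSIGNED rank"
                )

    def rank(self, name: str) -> str:
        return self.ranks[RANKS.index(name)]

    def truncated(self, last_rank: str) -> "TaxonLabel":
        """Copy with every rank below ``last_rank`` set to UNASSIGNED."""
        cut = RANKS.index(last_rank) + 1
        return TaxonLabel(self.ranks[:cut] + (UNASSIGNED,) * (len(RANKS) - cut))


EMPTY_LABEL = TaxonLabel((UNASSIGNED,) * len(RANKS))


def quality_tier(completeness: float, contamination: float) -> str:
    """Tier from CheckM-style completeness/contamination percentages."""
    if not 0.0 <= completeness <= 100.0:
        raise ArgumentError(f"completeness {completeness} outside [0, 100]")
    if not 0.0 <= contamination <= 100.0:
        raise ArgumentError(f"contamination {contamination} outside [0, 100]")
    if contamination < 5.0:
        if completeness > 90.0:
            return "high"
        if completeness > 50.0:
            return "medium"
    return "fail"


def _majority_label(labels: Sequence[TaxonLabel]) -> TaxonLabel:
    """Rank-by-rank plurality vote; a tie abstains from that rank down."""
    ranks: list[str] = []
    for i, _ in enumerate(RANKS):
        votes = Counter(lab.ranks[i] for lab in labels if lab.ranks[i] != UNASSIGNED)
        if not votes:
            break
        ordered = votes.most_common()
        if len(ordered) > 1 and ordered[0][1] == ordered[1][1]:
            break
        ranks.append(ordered[0][0])
    return TaxonLabel(tuple(ranks) + (UNASSIGNED,) * (len(RANKS) - len(ranks)))


def propagate_taxonomy(
    catalog: BinCatalog,
    reference_labels: Mapping[str, TaxonLabel],
) -> dict[str, TaxonLabel]:
    """Label every bin from its reference members, inheriting across levels.

    Returns a mapping ``bin_id -> TaxonLabel`` covering all SGBs, GGBs, and
    FGBs.  Raises :class:`ConsistencyError` if a kSGB has no labeled
    reference member.
    """
    sources = catalog.genome_sources
    sgbs = catalog.at_level("SGB")

    sgb_ref_labels: dict[str, TaxonLabel] = {}
    for sgb in sgbs:
        refs = [g for g in sgb.member_ids if sources.get(g) == "reference"]
        if sgb.novelty_class == "kSGB":
            labeled = [reference_labels[g] for g in refs if g in reference_labels]
            if not labeled:
                raise ConsistencyError(
                    f"kSGB {sgb.bin_id} has no labeled reference member"
                )
            sgb_ref_labels[sgb.bin_id] = _majority_label(labeled)

    def _vote_over_ksgbs(parent: GenomeBin, children: Sequence[GenomeBin], last_rank: str) -> TaxonLabel:
        child_labels = [
            sgb_ref_labels[c.bin_id]
            for c in children
            if c.bin_id in sgb_ref_labels
        ]
        if not child_labels:
            return EMPTY_LABEL
        return _majority_label(child_labels).truncated(last_rank)

    ggbs = catalog.at_level("GGB")
    fgbs = catalog.at_level("FGB")
    sgbs_of_ggb = {
        g.bin_id: [s for s in sgbs if s.parent_bin_id == g.bin_id] for g in ggbs
    }
    sgbs_of_fgb: dict[str, list[GenomeBin]] = {f.bin_id: [] for f in fgbs}
    for g in ggbs:
        sgbs_of_fgb[g.parent_bin_id].extend(sgbs_of_ggb[g.bin_id])

    labels: dict[str, TaxonLabel] = {}
    for g in ggbs:
        labels[g.bin_id] = _vote_over_ksgbs(g, sgbs_of_ggb[g.bin_id], "genus")
    for f in fgbs:
        labels[f.bin_id] = _vote_over_ksgbs(f, sgbs_of_fgb[f.bin_id], "family")
    for sgb in sgbs:
        if sgb.bin_id in sgb_ref_labels:
            labels[sgb.bin_id] = sgb_ref_labels[sgb.bin_id]
            continue
        ggb_label = labels[sgb.parent_bin_id]
        if ggb_label.rank("genus") != UNASSIGNED:
            labels[sgb.bin_id] = ggb_label.truncated("genus")
        else:
            fgb_id = catalog.by_id(sgb.parent_bin_id).parent_bin_id
            labels[sgb.bin_id] = labels[fgb_id].truncated("family")
    return labels


def assignment_level_summary(
    catalog: BinCatalog,
    labels: Mapping[str, TaxonLabel],
    mags: Sequence[MagCatalogEntry],
) -> pd.DataFrame:
    """Per-dataset counts of MAGs by deepest taxonomic assignment level.

    Every MAG lands in exactly one category: members of kSGBs are assigned
    at species level; members of uSGBs are known species-level units without
    a name; pSGB members count by the deepest inherited rank (genus, family,
    or nothing).
    """
    sgb_of = catalog.sgb_of_genome()
    novelty = {b.bin_id: b.novelty_class for b in catalog.at_level("SGB")}
    rows: dict[str, Counter] = {}
    for mag in mags:
        if mag.mag_id not in sgb_of:
            raise ConsistencyError(f"MAG {mag.mag_id!r} is not a member of any SGB")
        sgb_id = sgb_of[mag.mag_id]
        cls = novelty[sgb_id]
        if cls == "kSGB":
            cat = "species_known"
        elif cls == "uSGB":
            cat = "species_unknown_uSGB"
        else:
            label = labels[sgb_id]
            if label.rank("genus") != UNASSIGNED:
                cat = "genus_level"
            elif label.rank("family") != UNASSIGNED:
                cat = "family_level"
            else:
                cat = "unassigned"
        rows.setdefault(mag.dataset, Counter())[cat] += 1
    df = pd.DataFrame(
        [
            {"dataset": ds, **{c: counts.get(c, 0) for c in SUMMARY_CATEGORIES}}
            for ds, counts in sorted(rows.items())
        ]
    )
    df["n_mags"] = df[list(SUMMARY_CATEGORIES)].sum(axis=1)
    for c in SUMMARY_CATEGORIES:
        df[f"frac_{c}"] = df[c] / df["n_mags"]
    return df


def read_reference_labels(path: str | Path) -> dict[str, TaxonLabel]:
    """TSV with columns genome_id + the seven ranks -> label mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(UNASSIGNED)
    return {
        row.genome_id: TaxonLabel(tuple(getattr(row, r) for r in RANKS))
        for row in df.itertuples(index=False)
    }


def write_reference_labels(path: str | Path, labels: Mapping[str, TaxonLabel]) -> None:
    df = pd.DataFrame(
        [{"genome_id": g, **dict(zip(RANKS, lab.ranks))} for g, lab in labels.items()]
    )
    df.to_csv(path, sep="\t", index=False)
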