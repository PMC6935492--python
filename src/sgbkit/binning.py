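"""Genome-bin construction: species/genus/family clustering and novelty classes.

Genomes are clustered by average-linkage agglomeration on their pairwise
genetic distances.  Cutting the dendrogram at 5% distance yields
species-level genome bins (SGBs); SGB representatives (medoids) are
re-clustered at 15% into genus-level bins (GGBs) and GGB representatives at
30% into family-level bins (FGBs).  Clustering representatives rather than
all genomes guarantees that the three partitions nest.

Each SGB gets a novelty class from the provenance of its members:

* kSGB — contains at least one reference genome (a known species);
* uSGB — no reference, but contains human-derived MAGs (unknown species
  already seen in the human microbiome);
* pSGB — only non-human-primate MAGs (novel, primate-specific species).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import ArgumentError, ConsistencyError, ValidationError
from .io_formats import HOST_CATEGORIES
from .sketching import DistanceMatrix, Sketch, sketch_distance

NOVEL = "NOVEL"
LEVELS = ("SGB", "GGB", "FGB")
_HUMAN_CATEGORIES = frozenset({"human_westernized", "human_nonwesternized"})


@dataclass(frozen=True)
class GenomeBin:
    """A cluster of genomes at one taxonomic resolution level."""

    bin_id: str
    level: str  # SGB | GGB | FGB
    member_ids: tuple[str, ...]
    representative_id: str
    novelty_class: str = "not_applicable"  # kSGB | uSGB | pSGB at SGB level
    parent_bin_id: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ArgumentError(f"unknown bin level {self.level!r}")
        if self.representative_id not in self.member_ids:
            raise ArgumentError(
                f"bin {self.bin_id}: representative {self.representative_id!r} "
                "is not a member"
            )
        if (self.level == "SGB") == (self.novelty_class == "not_applicable"):
            raise ArgumentError(
                f"bin {self.bin_id}: novelty_class {self.novelty_class!r} "
                f"invalid for level {self.level}"
            )


@dataclass(frozen=True)
class BinCatalog:
    """All bins across the three levels plus genome provenance."""

    bins: tuple[GenomeBin, ...]
    genome_sources: Mapping[str, str]  # genome id -> host_category

    def at_level(self, level: str) -> list[GenomeBin]:
        return [b for b in self.bins if b.level == level]

    def by_id(self, bin_id: str) -> GenomeBin:
        for b in self.bins:
            if b.bin_id == bin_id:
                return b
        raise ConsistencyError(f"no bin with id {bin_id!r}")

    def sgb_of_genome(self) -> dict[str, str]:
        mapping: dict[str, str] = {}
        for b in self.at_level("SGB"):
            for g in b.member_ids:
                mapping[g] = b.bin_id
        return mapping


@dataclass(frozen=True)
class Assignment:
    """Placement of one new MAG against an existing bin catalog."""

    mag_id: str
    assigned_bin_id: str  # an SGB id, or NOVEL
    min_distance: float
    nearest_member_id: str


def _validate_matrix(dm: DistanceMatrix) -> None:
    # DistanceMatrix validates on construction; re-check here because callers
    # may hand-build instances via dataclasses.replace or mutate .values.
    v = dm.values
    if not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    if np.any(v < 0) or np.any(v > 1):
        raise ValidationError("distances must lie in [0, 1]")


def cluster_genomes(dm: DistanceMatrix, threshold: float) -> list[list[str]]:
    """Average-linkage clustering cut at ``threshold``; returns a partition.

    Ids are sorted before linkage so tie-breaking is lexicographic and the
    result is deterministic.  Clusters are ordered by their smallest member
    id; members within a cluster are sorted.
    """
    if not 0.0 < threshold < 1.0:
        raise ArgumentError(f"threshold {threshold} outside (0, 1)")
    _validate_matrix(dm)
    order = sorted(range(len(dm.ids)), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    if len(ids) == 1:
        return [[ids[0]]]
    values = dm.values[np.ix_(order, order)]
    z = linkage(squareform(values, checks=False), method="average")
    labels = fcluster(z, t=threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for gid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(gid)
    return sorted((sorted(m) for m in clusters.values()), key=lambda m: m[0])


def medoid(dm: DistanceMatrix, member_ids: Sequence[str]) -> str:
    """Member minimizing total distance to the others; ties -> smallest id."""
    if not member_ids:
        raise ArgumentError("medoid of an empty member list is undefined")
    idx = [dm.index_of(g) for g in member_ids]
    sub = dm.values[np.ix_(idx, idx)]
    sums = sub.sum(axis=1)
    best = min(range(len(member_ids)), key=lambda i: (sums[i], member_ids[i]))
    return member_ids[best]


def classify_sgb(member_ids: Sequence[str], genome_sources: Mapping[str, str]) -> str:
    """Novelty class of an SGB from its members' provenance."""
    categories = set()
    for gid in member_ids:
        if gid not in genome_sources:
            raise ConsistencyError(f"genome {gid!r} has no recorded host category")
        cat = genome_sources[gid]
        if cat not in HOST_CATEGORIES:
            raise ValidationError(f"genome {gid!r}: unknown host category {cat!r}")
        categories.add(cat)
    if "reference" in categories:
        return "kSGB"
    if categories & _HUMAN_CATEGORIES:
        return "uSGB"
    return "pSGB"


def make_sgbs(
    dm: DistanceMatrix,
    genome_sources: Mapping[str, str],
    threshold: float = 0.05,
) -> list[GenomeBin]:
    """Cluster all genomes at the species threshold and classify each bin."""
    partition = cluster_genomes(dm, threshold)
    width = max(4, len(str(len(partition))))
    bins = []
    for i, members in enumerate(partition, start=1):
        bins.append(
            GenomeBin(
                bin_id=f"SGB{i:0{width}d}",
                level="SGB",
                member_ids=tuple(members),
                representative_id=medoid(dm, members),
                novelty_class=classify_sgb(members, genome_sources),
            )
        )
    return bins


def build_hierarchy(
    sgbs: Sequence[GenomeBin],
    dm: DistanceMatrix,
    genome_sources: Mapping[str, str],
    ggb_threshold: float = 0.15,
    fgb_threshold: float = 0.30,
) -> BinCatalog:
    """Nest SGBs into GGBs (15%) and FGBs (30%) by clustering representatives.

    Because each level clusters only the representatives of the level below,
    a lower-level bin can never be split across parents and the partitions
    nest by construction.
    """
    if not sgbs:
        raise ArgumentError("no SGBs to build a hierarchy from")
    if not ggb_threshold < fgb_threshold:
        raise ArgumentError("thresholds must be strictly increasing (GGB < FGB)")

    def _cluster_level(
        children: Sequence[GenomeBin], threshold: float, prefix: str
    ) -> list[GenomeBin]:
        reps = [b.representative_id for b in children]
        by_rep = {b.representative_id: b for b in children}
        if len(reps) == 1:
            groups = [[reps[0]]]
        else:
            groups = cluster_genomes(dm.submatrix(reps), threshold)
        width = max(4, len(str(len(groups))))
        bins = []
        for i, rep_group in enumerate(groups, start=1):
            members = tuple(
                sorted(g for rep in rep_group for g in by_rep[rep].member_ids)
            )
            bins.append(
                GenomeBin(
                    bin_id=f"{prefix}{i:0{width}d}",
                    level=prefix,
                    member_ids=members,
                    representative_id=medoid(dm, rep_group),
                )
            )
        return bins

    ggbs = _cluster_level(sgbs, ggb_threshold, "GGB")
    fgbs = _cluster_level(ggbs, fgb_threshold, "FGB")

    def _parent_of(child: GenomeBin, parents: Sequence[GenomeBin]) -> str:
        for p in parents:
            if child.representative_id in p.member_ids:
                return p.bin_id
        raise ConsistencyError(f"bin {child.bin_id} has no parent")

    sgbs_linked = [replace(b, parent_bin_id=_parent_of(b, ggbs)) for b in sgbs]
    ggbs_linked = [replace(b, parent_bin_id=_parent_of(b, fgbs)) for b in ggbs]
    return BinCatalog(
        bins=tuple(sgbs_linked) + tuple(ggbs_linked) + tuple(fgbs),
        genome_sources=dict(genome_sources),
    )


def assign_to_catalog(
    mag_sketch: Sketch,
    catalog_sketches: Sequence[Sketch],
    catalog: BinCatalog,
    threshold: float = 0.05,
    *,
    medoid_only: bool = False,
) -> Assignment:
    """Place a new MAG into the nearest catalog SGB, or call it NOVEL.

    By default the MAG is compared against every catalog genome; with
    ``medoid_only`` it is compared against SGB representatives only.
    Distance ties are broken by the smallest SGB id.
    """
    sgb_of = catalog.sgb_of_genome()
    if not sgb_of:
        raise ArgumentError("catalog contains no SGBs")
    if medoid_only:
        reps = {b.representative_id for b in catalog.at_level("SGB")}
        candidates = [s for s in catalog_sketches if s.genome_id in reps]
    else:
        candidates = [s for s in catalog_sketches if s.genome_id in sgb_of]
    if not candidates:
        raise ArgumentError("no catalog sketches overlap the catalog SGBs")
    scored = [
        (sketch_distance(mag_sketch, s), sgb_of[s.genome_id], s.genome_id)
        for s in candidates
    ]
    d, bin_id, nearest = min(scored)
    if d <= threshold:
        return Assignment(mag_sketch.genome_id, bin_id, d, nearest)
    return Assignment(mag_sketch.genome_id, NOVEL, d, nearest)


def upgma_newick(dm: DistanceMatrix) -> str:
    """UPGMA dendrogram of the distance matrix as a newick string.

    Branch lengths are half the merge-height differences, so root-to-leaf
    depths are equal (ultrametric).
    """
    if len(dm.ids) < 2:
        raise ArgumentError("need at least 2 genomes for a dendrogram")
    _validate_matrix(dm)
    order = sorted(range(len(dm.ids)), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    values = dm.values[np.ix_(order, order)]
    z = linkage(squareform(values, checks=False), method="average")
    root = to_tree(z)

    def _render(node, parent_height: float) -> str:
        length = (parent_height - node.dist) / 2.0
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = _render(node.left, node.dist)
        right = _render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = _render(root.left, root.dist)
    right = _render(root.right, root.dist)
    return f"({left},{right});"


def catalog_to_tsv(catalog: BinCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_id\tlevel\tnovelty_class\trepresentative_id\tparent_bin_id\tmember_ids\n")
        for b in catalog.bins:
            fh.write(
                f"{b.bin_id}\t{b.level}\t{b.novelty_class}\t{b.representative_id}\t"
                f"{b.parent_bin_id or ''}\t{';'.join(b.member_ids)}\n"
            )
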