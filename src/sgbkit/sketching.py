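"""Alignment-free genome distances via bottom-s MinHash over canonical k-mers.

A genome is summarised by the ``s`` smallest 64-bit hash values of its
distinct canonical k-mers (the lexicographic minimum of each k-mer and its
reverse complement).  The Jaccard index of two genomes' k-mer sets is
estimated from the merged bottom of the two sketches, and converted to a
genetic distance with the Mash transform

    d = -(1/k) * ln( 2j / (1 + j) ),

which under a Poisson substitution model estimates the per-base divergence
between the genomes.  With sketch size 10,000 this supports species- (5%),
genus- (15%) and family-level (30%) clustering of genome bins.

Hashing uses a seeded splitmix64 finalizer over 2-bit-packed k-mer codes:
deterministic, uniform over 64 bits, and fast to vectorize.  The seed is
recorded in the sketch so incompatible sketches cannot be compared silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ArgumentError, IncompatibleSketchError
from .io_formats import SequenceRecord

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 10_000
DEFAULT_HASH_SEED = 42

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash signature of one genome's canonical k-mer set."""

    genome_id: str
    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray  # sorted ascending uint64, length min(s, n_kmers)
    n_kmers: int

    def compatible_with(self, other: "Sketch") -> bool:
        return (
            self.k == other.k
            and self.s == other.s
            and self.hash_seed == other.hash_seed
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric genome-by-genome genetic distance matrix in [0, 1]."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ArgumentError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ArgumentError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ArgumentError("distance matrix diagonal must be zero")
        if np.any(v < 0) or np.any(v > 1):
            raise ArgumentError("distances must lie in [0, 1]")

    def index_of(self, genome_id: str) -> int:
        return self.ids.index(genome_id)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index_of(g) for g in keep]
        return DistanceMatrix(tuple(keep), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for gid, row in zip(self.ids, self.values):
                fh.write(gid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
        return cls(tuple(header), np.array(rows, dtype=float))


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _splitmix64(values: np.ndarray, seed: int) -> np.ndarray:
    """Seeded splitmix64 finalizer, vectorized over uint64 codes."""
    with np.errstate(over="ignore"):
        z = values ^ np.uint64(seed & 0xFFFFFFFFFFFFFFFF)
        z = (z + np.uint64(0x9E3779B97F4A7C15)) * np.uint64(0xBF58476D1CE4E5B9)
        z ^= z >> np.uint64(30)
        z *= np.uint64(0x94D049BB133111EB)
        z ^= z >> np.uint64(27)
        z *= np.uint64(0x2545F4914F6CDD1D)
        z ^= z >> np.uint64(31)
    return z


def _encode_bases(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]

def kmer_codes(sequence: str, k: int) -> np.ndarray:
    """2-bit-packed codes of all valid (N-free) k-mer windows, in order.

    Big-endian packing (first base in the highest bits) preserves
    lexicographic order, so ``min(code, rc_code)`` picks the canonical
    strand.
    """
    if k <= 0:
        raise ArgumentError(f"k must be positive, got {k}")
    if 4**k > 2**63:
        raise ArgumentError(f"k={k} overflows 2-bit packing into 64 bits")
    codes_needed = len(sequence) - k + 1
    if codes_needed <= 0:
        return np.empty(0, dtype=np.uint64)
    base = _encode_bases(sequence)
    valid = base != 255
    window_valid = np.ones(codes_needed, dtype=bool)
    fwd = np.zeros(codes_needed, dtype=np.uint64)
    rev = np.zeros(codes_needed, dtype=np.uint64)
    base64 = base.astype(np.uint64)
    comp64 = (np.uint64(3) - base64) & np.uint64(3)
    for j in range(k):
        window_valid &= valid[j : codes_needed + j]
        fwd |= base64[j : codes_needed + j] << np.uint64(2 * (k - 1 - j))
        rev |= comp64[j : codes_needed + j] << np.uint64(2 * j)
    canonical = np.minimum(fwd, rev)
    return canonical[window_valid]


def forward_kmer_codes(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand 2-bit codes of valid k-mer windows plus their offsets.

    Unlike :func:`kmer_codes` this does not canonicalize the strand; it is
    the substrate for seed-and-extend read mapping where the two strands are
    queried separately.
    """
    if k <= 0:
        raise ArgumentError(f"k must be positive, got {k}")
    if 4**k > 2**63:
        raise ArgumentError(f"k={k} overflows 2-bit packing into 64 bits")
    codes_needed = len(sequence) - k + 1
    if codes_needed <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    base = _encode_bases(sequence)
    valid = base != 255
    window_valid = np.ones(codes_needed, dtype=bool)
    fwd = np.zeros(codes_needed, dtype=np.uint64)
    base64 = base.astype(np.uint64)
    for j in range(k):
        window_valid &= valid[j : codes_needed + j]
        fwd |= base64[j : codes_needed + j] << np.uint64(2 * (k - 1 - j))
    positions = np.nonzero(window_valid)[0]
    return fwd[window_valid], positions


def canonical_kmers(sequence: str, k: int) -> set[str]:
    """Distinct canonical k-mers of a sequence, as strings.

    Windows containing N (or any non-ACGT character) are skipped.
    """
    if k <= 0:
        raise ArgumentError(f"k must be positive, got {k}")
    result: set[str] = set()
    upper = sequence.upper()
    for i in range(len(upper) - k + 1):
        kmer = upper[i : i + k]
        if set(kmer) <= set("ACGT"):
            result.add(min(kmer, reverse_complement(kmer)))
    return result


def build_sketch(
    genome: Sequence[SequenceRecord],
    *,
    genome_id: str | None = None,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    """Sketch a genome (contigs pooled into one canonical k-mer set)."""
    if not genome:
        raise ArgumentError("cannot sketch an empty genome")
    if s < 1:
        raise ArgumentError(f"sketch size must be >= 1, got {s}")
    codes = [kmer_codes(rec.sequence, k) for rec in genome]
    pooled = np.unique(np.concatenate(codes)) if codes else np.empty(0, dtype=np.uint64)
    if pooled.size == 0:
        gid = genome_id or genome[0].id
        raise ArgumentError(f"unsketchable genome {gid!r}: no valid k-mers")
    hashes = np.unique(_splitmix64(pooled, hash_seed))
    return Sketch(
        genome_id=genome_id or genome[0].id,
        k=k,
        s=s,
        hash_seed=hash_seed,
        hashes=hashes[:s].copy(),
        n_kmers=int(pooled.size),
    )


def _require_compatible(a: Sketch, b: Sketch) -> None:
    if not a.compatible_with(b):
        raise IncompatibleSketchError(
            f"sketches {a.genome_id!r} (k={a.k}, s={a.s}, seed={a.hash_seed}) and "
            f"{b.genome_id!r} (k={b.k}, s={b.s}, seed={b.hash_seed}) are incompatible"
        )


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Bottom-s estimate of the Jaccard index of two genomes' k-mer sets.

    Merges the two sketches, keeps the ``s`` smallest distinct values X, and
    returns ``|X ∩ A ∩ B| / |X|``.  Exact when both genomes have at most
    ``s`` distinct k-mers.
    """
    _require_compatible(a, b)
    union = np.union1d(a.hashes, b.hashes)
    x = union[: a.s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    hits = np.intersect1d(x, shared, assume_unique=True).size
    return hits / x.size


def mash_distance(j: float, k: int) -> float:
    """Mash distance transform of a Jaccard estimate; capped at 1."""
    if not 0.0 <= j <= 1.0:
        raise ArgumentError(f"jaccard estimate {j} outside [0, 1]")
    if j == 0.0:
        return 1.0
    return min(1.0, -np.log(2.0 * j / (1.0 + j)) / k)


def sketch_distance(a: Sketch, b: Sketch) -> float:
    return mash_distance(jaccard_estimate(a, b), a.k)


def pairwise_distances(sketches: Sequence[Sketch]) -> DistanceMatrix:
    """All-vs-all Mash distances; zero diagonal, symmetric by construction."""
    if not sketches:
        raise ArgumentError("need at least one sketch")
    n = len(sketches)
    values = np.zeros((n, n))
    for i in range(n):
        for jdx in range(i + 1, n):
            d = sketch_distance(sketches[i], sketches[jdx])
            values[i, jdx] = values[jdx, i] = d
    return DistanceMatrix(tuple(s.genome_id for s in sketches), values)


def sketch_to_json(sketch: Sketch, path: str | Path) -> None:
    doc = {
        "genome_id": sketch.genome_id,
        "k": sketch.k,
        "s": sketch.s,
        "hash_seed": sketch.hash_seed,
        "hashes": [int(h) for h in sketch.hashes],
        "n_kmers": sketch.n_kmers,
    }
    Path(path).write_text(json.dumps(doc))


def sketch_from_json(path: str | Path) -> Sketch:
    doc = json.loads(Path(path).read_text())
    return Sketch(
        genome_id=doc["genome_id"],
        k=doc["k"],
        s=doc["s"],
        hash_seed=doc["hash_seed"],
        hashes=np.array(doc["hashes"], dtype=np.uint64),
        n_kmers=doc["n_kmers"],
    )
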