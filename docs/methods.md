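# Methods

## Genome distances

Genomes are compared alignment-free. Each genome's contigs are pooled into
one set of canonical k-mers (the lexicographic minimum of each k-mer and
its reverse complement; windows containing N are skipped), and the genome
is summarized by the `s` smallest 64-bit hashes of that set (bottom-s
MinHash). The Jaccard index `j` of two k-mer sets is estimated from the
merged bottom of the two sketches — take the `s` smallest distinct hashes
of the union X and return |X ∩ A ∩ B| / |X| — which is exact whenever both
genomes hold at most `s` distinct k-mers. The genetic distance is the Mash
transform

    d = -(1/k) * ln( 2j / (1 + j) ),

the Poisson-model estimate of per-base divergence; `j = 0` is capped at
d = 1 since the logarithm diverges. Defaults: `k = 21` (the customary
genome-scale k-mer length, long enough that random 21-mer collisions are
negligible at ~Mb genome sizes), `s = 10,000`, hash seed 42. The hash is a
seeded splitmix64 finalizer applied to the 2-bit-packed k-mer code;
big-endian packing makes integer order coincide with lexicographic order,
so canonicalization is a single `min`. The seed and parameters are stored
in every sketch and checked on comparison.

Under exact-count substitution at fraction p, the expected distance is
−ln(1−p) ≈ p + p²/2; the bias reaches 0.003 at p = 0.08 and the bottom-s
sampling noise adds ~0.001–0.003, which is why the accuracy contract is a
*median* absolute error ≤ 0.005 over pairs spanning p = 0.01–0.08.

## Genome-bin hierarchy

Genomes are clustered by average-linkage agglomeration on the distance
matrix (scipy's hierarchy implementation), cutting the dendrogram so that
clusters merge while their average inter-cluster distance stays at or
below the threshold. Species-level genome bins (SGBs) use 5%; this is the
operational species definition for MAG catalogs. Genus- (15%) and
family-level (30%) bins are built by re-clustering *representatives*
(medoids — the member minimizing total intra-bin distance, ties to the
lexicographically smallest id) of the level below. Clustering
representatives rather than all genomes guarantees the three partitions
nest: a lower-level bin can never be split between two parents. The
alternative — independent clustering of all genomes at each threshold —
was rejected precisely because it can split SGBs across GGBs.

Ids are sorted before linkage and all ties break lexicographically, so
partitions, bin ids (`SGB0001`… in cluster order), and dendrograms are
deterministic for a given input.

New MAGs are assigned to an existing catalog by minimum distance to *any*
catalog member (a conservative reading of membership); an optional
medoid-only mode compares against representatives instead. A MAG farther
than the threshold from everything is NOVEL. Loosening the threshold can
only convert NOVEL calls to assignments, never the reverse.

Novelty classes are decided by member provenance with a fixed priority:
any reference genome in the bin makes it a kSGB; otherwise any
human-derived MAG makes it a uSGB; otherwise it is a pSGB. The three
classes are exhaustive and mutually exclusive.

## Quality tiers and taxonomy

Quality tiers take CheckM-style completeness/contamination percentages as
given (estimating them is out of scope): high requires completeness > 90
and contamination < 5, medium completeness > 50 and contamination < 5,
both inequalities strict, read literally from the tier definitions.

Taxonomy propagates from reference genomes only. A kSGB takes a
rank-by-rank plurality vote over its references' seven-rank labels
(kingdom…species); a tie abstains — UNASSIGNED at the tied rank and
everything below, keeping labels internally consistent (no rank is
assigned below an unassigned one). SGBs without references inherit the
majority genus of the kSGBs sharing their GGB, or failing that the
majority family of the kSGBs sharing their FGB, and are UNASSIGNED below.
This bin-co-membership inheritance is a documented approximation of
marker-gene placement, which is out of scope. The per-MAG summary buckets
every MAG into exactly one of: species-known (kSGB), species-unknown
(uSGB), genus-level, family-level, or unassigned.

## Mappability

Per sample: subsample the raw reads at 1% (floor(0.01·n) reads drawn
uniformly without replacement, seed recorded), remove host-mapping reads,
drop reads shorter than 70 bp or with mean Phred below 20 (boundary reads
— exactly 70 bp, mean exactly 20 — survive), then map the surviving
high-quality reads incrementally against ordered tiers: reference
genomes, then human-derived bins, then primate-specific bins. A read is
attributed to the first tier it maps to; later tiers only see what is
still unmapped, so the per-tier counts partition the high-quality reads
and the conservation identity sum(mapped) + unmapped = n_hq holds by
construction. Mappability is mapped/high-quality; catalog gain is the
percent change of that fraction over a baseline (undefined — reported as
an error, not a division — when the baseline is zero).

The mapper is a deterministic seed-and-extend pseudo-aligner: exact
31-mer seeds (every offset of the read, both strands) locate candidate
ungapped end-to-end placements, scored 0 per match and −6 per mismatch;
a read maps when its best score is ≥ −20, i.e. at most 3 mismatches.
The −6/−20 pairing translates the usual end-to-end alignment-score
cutoff into a mismatch budget. It has no gaps — synthetic reads carry
substitution errors only — and sits behind a small index interface so a
full aligner could be substituted for real data.

## Enrichment statistics

Feature presence is binary per sample (an SGB is present where at least
one of the sample's MAGs belongs to it). For two groups, each feature's
2×2 presence-by-group table gets a two-sided Fisher's exact p-value by
the point-probability method: the sum of hypergeometric point
probabilities not exceeding that of the observed table. Point weights are
compared as exact big integers (binomial coefficients over a common
denominator), so tie decisions are exact and the only rounding is the
final rational-to-float conversion; results agree with scipy's
implementation to < 1e-12 over all small tables and are cached per table.
Presence gates (minimum count in each group; minimum total count) are
applied *before* testing, so the multiplicity burden counts only tested
features. Bonferroni and Benjamini–Hochberg adjustments come from
statsmodels. The KO prevalence band keeps features present in at least
20% and less than 80% of samples (inclusive lower, strict upper bound).

## Synthetic data

The generator plants exactly the structure the pipeline estimates. A root
genome is i.i.d. with configurable GC; species genomes evolve from it at
*half* the configured inter-cluster divergence and MAG genomes from their
species at half the intra-cluster divergence, so the planted *pairwise*
divergences (what the clustering thresholds act on) equal the configured
values under the star phylogeny. Evolution is substitution-only with an
exact site count (round(d·L) positions, each changed to a different
base), so planted divergence is the Hamming fraction with no noise.

MAGs are non-overlapping contig windows (one per equal genome block)
totalling the drawn completeness, plus foreign windows from other species
contributing the drawn contamination fraction of assembled length.
Defaults (5 species, 50 kb genomes, 2%/10% divergence, 4 MAGs per
species, completeness 80–100%, contamination 0–3%) describe a
medium-to-high-quality MAG catalog: at 50 kb, sub-50% completeness would
leave too few shared k-mers for stable distance estimates, which is a
genome-size artifact of desk-scale genomes, not a property of real Mb
genomes. Reads have uniform starts, random strand, per-base substitution
errors, and two-level qualities (Phred 30 correct / 15 error) so the
mean-quality filter is triggerable by construction.

Cohorts draw per-sample species presence from planted per-group
prevalences; MAG-bearing samples are always marked present, but presence
is deliberately denser than MAG recovery (as in real data, where a
species occurs in more samples than it can be assembled from). Matrix-
scale enrichment studies (hundreds to thousands of samples) use the
lighter `simulate_presence_cohort`, which emits the presence matrix
directly. All randomness derives from one scenario seed through stable
labeled sub-seeds (CRC32 of the label XOR the seed, kept below 2³¹), so
cohorts are byte-identical across reruns.

What the generator does **not** emulate: indels and rearrangements,
quality decay along reads, non-uniform coverage and abundance
distributions, paired ends, chimeric contigs, horizontal transfer. Tests
passing on this material validate the estimators and accounting under
their stated models, not robustness to those real-data complications.

## Numerical and reporting choices

Percentages are rounded half-away-from-zero to one decimal (two where
the quantity is conventionally printed with two), with raw fractions
always emitted alongside; comparisons are at value level. Distances are
validated to be symmetric, in [0, 1], and zero-diagonal on construction.
Every pipeline output embeds a hash of the effective configuration, which
is itself dumped with no hidden defaults; logs go to standard error,
results never do.

Problem sizes in the test suite and acceptance script (50 kb genomes,
20-MAG cohorts, 2000-read samples, 200 × 2200 presence matrices, 50 null
replicates) were chosen as the smallest scales at which each planted
effect is comfortably identifiable; all complete in seconds on one CPU.

## Known limitations

* The pseudo-mapper is ungapped and substitution-only; scores are not
  comparable to a full aligner's on indel-bearing reads.
* Genus/family taxonomy inheritance via bin co-membership is coarser
  than marker-gene placement and can only label bins that share a GGB or
  FGB with a reference-bearing bin.
* Assignment of new MAGs does not re-cluster the catalog; incremental
  catalog updating is out of scope.
* Fisher tests pool samples across datasets; treating datasets as the
  experimental unit would change the question being asked and is not
  implemented.
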