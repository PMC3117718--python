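# Methods

## Duplicate model and detection

Artificial duplicates on the 454 platform arise when one DNA fragment is
read several times: the resulting reads start at the same position on
the same strand and are near-identical, differing by homopolymer
over/under-calls (the platform's dominant indel mode), occasional
substitutions, and different stop positions. Reads from *different*
fragments that merely happen to start nearby are much less alike — the
premise that makes co-start similarity a usable duplicate signal.

Detection proceeds in four steps:

1. **Candidate seeding.** Reads are bucketed by their first `seed_k`
   bases (default 16); every within-bucket pair is a candidate. This is
   exact for pairs that agree over the seed region and O(n) in the
   number of reads, but blind to pairs whose very first bases differ:
   an error inside the seed region hides a true duplicate. `seed_k` is
   a sensitivity/speed compromise and is configurable. Seeding is
   forward-strand only, which enforces the same-strand requirement
   structurally.
2. **Co-start scoring.** Candidates are scored by a banded global
   alignment anchored at offset 0 of both reads, consuming the whole
   shorter read and ending anywhere within the band on the longer one.
   Weights are match +1, mismatch −2, gap −3 per gapped base —
   approximating megablast-style defaults so that a score threshold of
   100 means roughly "100 matching bases". Band half-width is 8
   diagonals; paths that would leave the band are truncated at the last
   in-band cell. Duplicates differ by few indels, so the band is rarely
   binding.
3. **Edge criteria.** An edge requires score strictly above
   `score_threshold` (default 100) and, unless `aggressive` is set,
   length difference strictly below `length_diff_max` (default 70
   bases). Both bounds are strict by definition. A consequence of the
   defaults: reads shorter than 101 bases can never be flagged.
4. **Clustering.** Connected components over all reads (via networkx)
   are the duplication clusters; the longest member is kept, ties
   broken by lexicographically smallest id for determinism. Cluster
   order follows first appearance in the input.

Two caveats delimit what the method can see. Reverse-complement
duplicates are out of scope by design (454 duplicates share the strand).
And the co-start score itself cannot distinguish a duplicate from a
distinct fragment starting within a few bases: an overlap at offset *d*
costs 3·*d* in leading gaps and can still clear the threshold for small
*d*. In dense read sets such neighbours can be joined — by this
implementation within its ±8-diagonal band, and by any unbanded scorer
up to *d* ≈ (ℓ − 100)/4. This is a property of the edge definition, not
of the banding.

## Paired-end decision tree

Linkers are located with a plain Smith–Waterman local aligner (same
+1/−2/−3 weights), each linker on both strands; per linker the best hit
is taken, its span masked, and the search repeated, after which hits
from all linkers are merged greedily by score (ties to the leftmost)
into a non-overlapping set. A hit is *full* when it spans the entire
linker with at most `full_mismatch_max` (default 2) mismatches+gaps;
hits covering less than half the linker are treated as noise and
dropped.

The seven cases: no hit → keep whole as single; ≥ 2 hits → discard; one
partial hit within `end_margin` (default 5 bases) of a read end → clip
it and keep the longer flank (tie → left); one internal partial hit →
discard; one full hit with both flanks ≥ `min_end_len` (default 50) →
emit the pair; with exactly one long-enough flank → keep that flank;
with neither → discard. The numeric thresholds are tool conventions,
not platform constants, and all are exposed as flags. Repeated hits of
one linker and hits of distinct linkers are treated alike (discard on
two or more). Pair halves are named `id/1` (left of the linker in read
orientation) and `id/2`, the common assembler convention.

## Basic filters

* **Length window**: keep iff `length_min ≤ len ≤ length_max`
  (inclusive; defaults 50–1000).
* **Length by deviation**: keep iff within mean ± k·σ (default k = 2)
  of the length distribution of *all* input reads, with σ the
  population (÷N) standard deviation, both computed before any removal.
* **Complexity**: 100 × (zlib-compressed byte length at level 9, minus
  the 8-byte empty-input overhead) ÷ read length. Subtracting the codec
  overhead keeps short reads comparable; maximum compression is fixed
  for reproducibility. Uniform-random DNA scores ≈ 65 at 50 bp falling
  to ≈ 35 at 1000 bp (DEFLATE's per-base cost shrinks with length);
  homopolymer through tetramer repeats score below 8 at any length.
  The default threshold 20 separates the two regimes at every 454-range
  read length. The windowed variant flags a read as complex if any
  100-base window (step 50; final window counted when at least half a
  window long) clears the threshold.
* **Quality**: a read is kept if at least one base quality is strictly
  above the threshold (default Phred 20) — the literal "no base above
  threshold" discard rule. It is deliberately permissive; a
  mean-quality criterion would be stricter but is a different filter.
* **N rate**: keep iff the fraction of Ns is ≤ `n_rate_max`
  (default 2%).

## Pipeline accounting

Stages run in a fixed order: paired-end splitting (it rewrites the read
set), then length, Ns, complexity, quality, duplicates. Each input read
receives exactly one fate; a read failing several filters is charged to
the first, so per-reason counters plus kept reads sum to the input
count. After splitting, later filters apply to the derived fragments; if
any fragment of a read fails, the whole read is charged to that stage
and none of its fragments is emitted (a pair is only ever written
whole). Duplicate removal after splitting treats fragments as reads; a
read whose fragment loses to a representative elsewhere is charged to
the duplicate stage. The log is a TSV of (id, fate, detail) plus a
footer with the summary counts and the cluster-size histogram; a
timestamp line is optional so runs can be byte-identical. The histogram
plot is cosmetic and untested.

## Simulator

`random_genome` draws a uniform i.i.d. genome; `simulate_shotgun_reads`
draws reads with uniform start and strand, reverse-complementing
minus-strand reads, optionally adding per-base substitutions and ±1
homopolymer-run indels. `inject_duplicates` copies chosen templates with
the same perturbations plus end truncations, returning the truth
clusters; a `protect_prefix` argument exempts the first bases from
perturbation, matching the seeding model's stated sensitivity domain.

Defaults emulate a full Titanium run: 671,856 reads of 500 bp from a
4.6 Mb genome (the size of the *E. coli* K12 genome commonly used for
validation runs). A uniform random genome stands in for the real one
deliberately: the chance-duplication null depends only on genome length,
and a synthetic sequence avoids rRNA-operon/IS-element repeat families
that would add co-start coincidences a random-selection model does not
intend. The per-run read count of the original half-plate experiments is
not public; the default simulates the full printed total.

"Replication rate" admits two readings, and both are reported: the
*membership* rate (fraction of reads in clusters of size ≥ 2, the
headline number) and the *removal* rate ((N − #clusters)/N, the fraction
actually discarded). At the default scale the membership rate is ≈ 7%,
matching the birthday closed form 1 − exp(−(n−1)/M) with
M = 2·(L − ℓ + 1) ≈ 9.2 × 10⁶ cells.

`replication_experiment` exploits that error-free reads from one
(start, strand) cell are exact copies: clustering reduces to hashing the
cells, which handles the full-scale run in under a second. Every run
verifies the fast path against the alignment-based pipeline on a
10,000-read subsample and raises if they disagree.

## Numerical and design choices

* Coordinates are 0-based half-open throughout; SFF's 1-based clip
  points are converted on ingest, taking the intersection (max of left
  clips, min of positive right clips) when both quality and adapter
  clips are set.
* FASTQ is Sanger/Phred+33 only; SFF is read-only (v1, flowgram format
  1), with flow values parsed and discarded. SFF *writing* is excluded:
  the historical route ran through Roche's `sfffile`, and FASTQ is the
  fallback output here as it was there.
* Characters outside {A, C, G, T, N} are uppercased and mapped to N
  with a logged warning.
* Degenerate inputs: empty files yield empty outputs and zero counters;
  the σ-length filter is a no-op below two reads; quality-less reads
  pass the quality filter with a warning; empty sequences are rejected
  at construction.
* Oracle-equivalence testing (seeded banded pipeline vs unbanded
  all-pairs DP) uses 200 reads of 300 bp on a 5 Mb genome — sparse
  enough that no two shotgun reads co-start by chance (asserted from
  the ground truth), which is the regime where the equivalence is
  defined. The recovery benchmark aggregates 100 replicates of 12 reads
  with four injected clusters each.

## What the synthetic data does not show

The simulator reproduces the geometry of random fragmentation, not the
454 error process: no flow-space simulation, no position-dependent
quality decay, constant qualities only. Passing the recovery tests shows
the clustering recovers duplicates under the modelled perturbations
(substitutions, homopolymer indels outside the seed region, truncations
under the length gate); it does not bound sensitivity on reads whose
first bases are themselves miscalled, nor on libraries with non-random
fragment ends (AFLP, 3' tags, reduced-representation), where genuine
co-starting fragments are indistinguishable from artifacts by this — or
any — co-start criterion.
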