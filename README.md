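# pyroclean

Cleaning of Roche 454 pyrosequencing reads before assembly or alignment.

454 runs carry a platform bias: a single DNA fragment can yield several
near-identical reads ("artificial duplicates"), inflating the apparent
abundance of that fragment. `pyroclean` removes them, splits paired-end
reads at their linker, and applies the usual length / complexity /
quality / undetermined-base filters. A built-in simulator implements the
random-fragmentation null model so observed duplication levels can be
compared with what random shearing alone would produce.

## Method

**Duplicate removal.** Artificial duplicates start at the same genomic
position on the same strand. Reads sharing their first *k* bases
(default *k* = 16) are aligned with a banded dynamic-programming
extension anchored at the first base of both reads (match +1,
mismatch −2, gap −3 per base, band ±8). An edge joins two reads when the
score exceeds 100 and their length difference is below 70 bases (the
`--aggressive` switch drops the length criterion). Connected components
of this graph are duplication clusters; only the longest read of each is
kept.

**Paired-end splitting.** Each of the supplied linkers is located in the
read by Smith–Waterman local alignment on both strands. A seven-case
decision tree then keeps linker-free reads as singles, discards reads
with multiple linker hits, clips partial linkers found at a read end,
emits a mate pair (`id/1`, `id/2`) when a complete linker sits with at
least 50 usable bases on each side, and salvages one flank when only one
side is long enough.

**Null model.** Drawing n reads of length ℓ uniformly from both strands
of a genome of length L gives M = 2·(L − ℓ + 1) possible (start, strand)
cells; the fraction of reads sharing a cell with another — the chance
"replication rate" — follows the birthday approximation
1 − exp(−(n−1)/M).

## Worked example

```
$ pyroclean replication-experiment --seed 2 --genome-len 4600000 \
      --n-reads 671856 --read-len 500
n=671856 membership=7.02% removal=3.55% expected=7.04% max_cluster=4
```

671,856 random 500 bp reads from a 4.6 Mb genome put ~7% of reads into
duplication clusters purely by chance (matching the closed form 7.04%),
with no cluster larger than a handful of reads — the baseline against
which a real run's duplication profile should be judged.

```
$ pyroclean clean --in reads.fastq --out run1 \
      --clean-length-win 50,1000 --clean-ns --clean-complexity-full \
      --clean-quality-full --clean-duplicated-reads --no-timestamp
input 20 reads; kept 12; length: 2; ns: 1; complexity: 1; quality: 2; duplicate: 2
```

Each removed read is charged to the first filter it violates, so the
per-reason counts plus the kept reads always sum to the input size. The
cleaned reads land in `run1_clean.fastq`; `run1.log` holds one row per
read with its fate plus a summary and the duplication cluster-size
histogram. Paired-end mode (`--clean-pairends --linkers linkers.fasta`)
writes `<prefix>_pairs.fastq` and `<prefix>_singles.fastq` instead; a
documented example linker file ships in `src/pyroclean/data/` (verify
the sequences against your chemistry before use).

Input may be FASTQ, FASTA (with an optional `.qual` sidecar) or a
454 SFF v1 file, whose quality/adapter clip points are applied on
ingest. Output is FASTQ or FASTA.

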