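# Methods

## Model: the expected in-file mate gap

In a coordinate-sorted alignment file the two mates of a paired-end
template are separated by other records.  Let *d* be the mean sequencing
depth, *t* the mean absolute template length and *l* the read length.
Each reference position is covered by *d* reads of length *l*, so *d/l*
read ends start per forward-strand position; the forward-strand start
points of the two mates of one template are *t − l* apart.  The expected
number of alignments between the mates is therefore

    E[gap] = (d / l) · (t − l)

(`expected_pair_gap`).  The model assumes uniform coverage and
well-formed pairs; real files violate both locally (coverage peaks, split
pairs), which is exactly why the engine has an overflow path.  The
statistic `empirical_mate_gap` computes the observed median and mean of
|rank₂ − rank₁| − 1 over templates whose mates are both mapped to the
same reference.

## The collation engine

Records stream through a fixed-size collisionless hash table `H` and a
fixed-size overflow list `L`; unresolved records spill to name-sorted
temporary runs that are k-way merged at the end.  Structure details:

* `H` = ring buffer `R` (serialized records, 4-byte length prefix,
  wrapped writes allowed) + slot table `P` (name-hash → offset in `R`,
  or empty) + ordered offset index `B` + insert cursor `r`.  An insert
  writes at `r`; if the circular gap between `r` and the next live offset
  in `B` is too small, the record at that successor offset is evicted to
  `L`, repeatedly, until the gap suffices.  The ordered index is a plain
  sorted Python list maintained with `bisect`; at the default 2¹⁶ slots
  its O(√n)-ish insertion cost is negligible against serialization.
* `L` packs record bytes from the front of its buffer and fixed 8-byte
  (offset, length) pointer entries from the back; it is full when the two
  regions would meet.  A flush sorts the pointer entries in place by the
  name comparator, emits complementary mates that became adjacent, and
  writes the remainder to a new temp run.
* The name comparator is bytewise-lexicographic on the raw name, with
  ties broken read1-before-read2, then source rank.  The hash is FNV-1a
  64-bit reduced mod *h* — fixed and configuration-independent, so runs
  are reproducible.
* Temp runs are length-prefixed serialized records behind a versioned
  magic header, uncompressed.  The merge validates sortedness while
  reading and fails hard on a corrupt run.  Runs are deleted after a
  successful merge.

Eligibility: secondary (0x100) and supplementary (0x800) alignments are
excluded from pairing — a name could otherwise carry more than two
records — and pass through as SINGLE, as do reads without the paired
flag; neither enters `H` or `L`.  QC-fail (0x200) records participate
normally, with the flag passed through.  A pair is always emitted
ordered (read1, read2) regardless of encounter order.

Defaults: h = 2¹⁶ slots, ring 16 MiB, list 32 MiB, one merge pass.  The
config field `k` is realised as a merge fan-in bound (256 open runs):
extra merge passes are inserted automatically only when a degenerate list
size produces more runs than the fan-in allows.  `tmp_dir` falls back to
the `BAMCOLLATE_TMPDIR` environment variable, then the system default.

Counters: `n_H` counts records whose pair resolved directly in `H`;
`n_L` counts every transit of the overflow list, including the final
drain of `H`, so with a single hash slot and no adjacent mates `n_L`
reaches `n`.  Peak live ring bytes and peak list occupancy are recorded
for instrumentation and asserted in tests.

## BAM→FastQ

Conversion restores the sequencing orientation (reverse-strand records
are reverse-complemented over the IUPAC alphabet and their quality string
reversed) and writes four files: index-aligned pair files, orphans,
singles — all always created, optionally gzip.  Secondary/supplementary
records are skipped (they would duplicate the primary read), as are
records storing no sequence ("*"), both with counters.  Output is
Phred+33.  Read names are bare by default; `--mate-suffix` appends /1
and /2.

## Duplicate marking

The 5′ coordinate of a record is the *unclipped* 5′ end on the
reference: leftmost position minus leading soft/hard clips on the
forward strand, rightmost aligned position plus trailing clips on the
reverse strand — so PCR copies with different clipping still collide.
Pairs (both ends mapped) are keyed by the lexicographically ordered pair
of end coordinates; each mapped end also contributes a pair-member
fragment entry.  Orphans (mate unmapped or absent) and singles
contribute plain fragment entries.  Scores sum base-quality values of at
least 15 (lower bases contribute 0; absent qualities score 0); pair
score is the sum of the two ends.  Per identical-coordinate class the
highest score wins representant status, ties to the lowest source rank.
Fragment classes: a non-pair fragment whose coordinate matches a mapped
pair's end is marked unconditionally (pair-protection is applied first;
with a pair present there are no survivors left to dedup); pair members
are never marked through the fragment list.

Memory is bounded by an entry threshold: when exceeded, the in-memory
class with the lowest coordinate is appended to a disk run and the
coordinate is handled externally from then on (one run per spilled
coordinate, hence trivially coordinate-sorted).  Finalization merges
in-memory classes and runs into coordinate-sorted flat lists and applies
the marking operators.  The marked-rank set is provably independent of
the threshold, which the tests assert for thresholds 1, 8 and unbounded.

Marking is two-pass: pass 1 collates and deduces the rank set (rank =
line number in the input); pass 2 rewrites the file with 0x400 set on
exactly those ranks and cleared elsewhere — pre-existing duplicate flags
are recomputed, making the operation idempotent.  All reads share one
namespace: no library/read-group partitioning (documented limitation).
Unmapped-only templates and secondary/supplementary records are never
marked.

## Synthetic data

The generator emulates the record-level phenomena the algorithms react
to, with rates fixed per profile: templates placed uniformly on
`n_refs` references of `genome_len` bases; template lengths normal
(t_mean, t_sd) truncated below at the read length; template count
d·genome_len·n_refs/(2l).  Categories per template: normal pair, orphan
(one mate emitted, flagged mate-unmapped), split pair (mates on distinct
references), single-end.  Duplicates are exact coordinate clones with
independently resampled qualities — the duplicate definition is
coordinate-based, matching the marking criterion, so cloned bases need
not match and the planted representant (highest score) is recoverable.
CIGARs are pure matches except an optional soft-clip mode that shifts
stored positions while leaving unclipped 5′ coordinates invariant.
Qualities are uniform in [20, 41); there is no sequencing-error model,
no quality-by-cycle structure and no real reference — so passing tests
demonstrate algorithmic correctness on the record level, not robustness
to aligner idiosyncrasies.  A fixed seed fixes the full output; the
truth table (one row per template clone: name, category, cluster id,
planted 5′ coordinates) is serialized as plain TSV.

## Test sizing and numerical choices

Oracle-equivalence checks run 20 generated files (sixteen of ~10³,
three of ~10⁴, one of ~10⁵ records) against a full name-sort-and-group
oracle across the 3×3 grid h ∈ {1, 16, 2¹⁶} × s_L ∈ {1, 64, 4096}
records; the formula-vs-simulation check uses a 10⁶-base genome at
depth 45 (≈ 4.5·10⁵ records) and a 3-standard-error band.  Duplicate
marking is cross-checked against an independent O(n²) all-pairs
implementation on ≤ 200-record files and against planted clusters on a
genome large enough (2·10⁵ bases at depth 2) that chance coordinate
collisions are absent.  Degenerate inputs covered: empty files, empty
lists/tables, single-record runs, records larger than a buffer (hard
error), unsorted temp runs (hard error), ties in scores (lowest rank
wins, deterministically).
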