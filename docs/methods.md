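# Methods

This note documents the models and algorithms behind chunkprof, the
parameter defaults and why they are what they are, the numerical and design
choices that were genuinely open, and what the synthetic validation does and
does not demonstrate.

## Reference preparation

Sequences whose names contain a blacklist substring (default: `plasmid`,
case-insensitive) are dropped before anything else; plasmids move between
genomes and systematically create cross-species matches. The remaining
contigs are joined with `k−1` bases of `N` between them, and any k-mer
window containing a non-ACGT character is discarded, so concatenation can
never manufacture k-mers that exist in no contig. `genome_size` counts only
real bases of the kept sequences (spacers excluded); it is the denominator
of the abundance normalization, so inflating it with bookkeeping characters
would bias abundances of fragmented assemblies downwards.

Chunking uses equal widths `w = ⌈(L + (n−1)·v) / n⌉` with overlap `v` and
stride `w − v`; the last chunk is clipped to the genome end. The overlap
(default 150 bp) should match the read length: every read then lies
entirely within at least one chunk, so an exact read always reaches k-mer
coverage 1.0 somewhere. Genomes too short to split meaningfully
(`L < n + v` or `L < 2n`) are kept as a single chunk with its actual chunk
count recorded — small viral genomes must remain indexable — and the
profiler always uses actual chunk counts, never the nominal 10.

### k-mer hashing

Canonical k-mers (lexicographic minimum of k-mer and reverse complement;
with the 2-bit code A=0 < C=1 < G=2 < T=3 the numeric minimum of the packed
words) are mixed through the splitmix64 finalizer to a 64-bit hash. The
scheme is identified as `splitmix64-2bit-v1` in every container and index
header, and searches refuse an index whose hash identifier differs from the
query side. The choice of a packed-word avalanche hash over a rolling hash
is deliberate: it is trivially reproducible across platforms and its full
avalanche behaviour is what the Bloom-filter analysis below assumes.
`k ≤ 32` is enforced by the 2-bit packing; the default `k = 21` balances
specificity against tolerance of point mutations.

## Bit-sliced Bloom index

Chunks are sorted by ascending k-mer count and filled into blocks of at
most `N` columns (default 32). Each block stores an `m × ⌈N/8⌉` uint8
matrix; column `c` occupies bit `c mod 8` of byte `c div 8` (little-endian
within the byte — fixed so files are bit-exact across machines). `m` is the
smallest filter length whose analytic false-positive rate
`(1 − e^{−hn/m})^h` does not exceed the requested `f` for the block's
*largest* chunk, so every other column enjoys the same or a lower rate. The
closed form `m = ⌈−n/ln(1−f)⌉` (h = 1) seeds the search but minimality is
enforced by a local scan, since float rounding near exact solutions (e.g.
`f = 1 − 1/e`, where `m = n`) can otherwise be off by one.

Because blocks size their filters independently, a run of very large
chunks at the tail of the sorted order would inflate `m` for every chunk
sharing their block. Three size thresholds therefore close a block early
when crossed; their default placement — geometric steps ×4, ×16, ×64 above
the median chunk k-mer count — was a free choice (no external guidance
exists) made so that thresholds only activate for genuinely atypical chunks
in collections that are heterogeneous by orders of magnitude. They are
fully configurable.

With `h > 1`, probe positions derive from the single stored 64-bit hash by
double hashing, `pos_i = (x + i·s(x)) mod m` with `s(x)` an odd step mixed
from `x`; only one hash per k-mer is ever stored. The default `h = 1`,
`f = 0.3` follows the trade-off documented below: a small index and fast
queries, with query-level significance restored by the binomial argument.

Block files are written one per block plus a `meta.json`, and blocks are
independently loadable and queryable; results are identical under any block
visit order or partition of the same database at the same filter size
(asserted by test).

## Pseudo-mapping and the query false-positive calculus

A query's ℓ distinct canonical k-mers (union over mates for pairs) are
counted against every column; a chunk is reported when `m/ℓ ≥ t` (default
`t = 0.55`) and `m` is at least an absolute floor. Ties in coverage are
broken lexicographically by (reference, chunk) for determinism.

Per k-mer the Bloom false-positive rate is `f`, but matches of distinct
k-mers are independent probes, so the probability that a chunk containing
*none* of the query's k-mers still reaches the threshold is the strict
binomial tail

    P(X > m),  X ~ Binomial(ℓ, f),

computed exactly (`scipy.stats.binom.sf`; an independent direct-summation
oracle cross-checks it in the tests). At `f = 0.3` this gives 5.30×10⁻¹⁰
for ℓ = 130, m = 72 (a 150-bp read at threshold), 9.51×10⁻⁷ for ℓ = 80,
m = 44, and 1.59×10⁻³ for ℓ = 10, m = 7 (a 30-bp read). The strict
inequality (`> m`, not `≥ m`) is part of the definition here — it is the
convention under which those three reference values are exact. Note the
calculus is not tight in one respect: k-mers genuinely present in a chunk
but originating from different regions of it also produce spurious
full-chunk matches; chunk-level coverage filtering in the profiler is the
defence against that.

The documented coverage equivalences (0.55 ≈ 96.5 % identity, 0.75 ≈ 98 %)
are treated as rules of thumb only; no identity model is implemented.

An optional "main matches" filter keeps, per read, only matches within a
coverage gap (default 0.2) of the read's best match. The gap value is a
package choice: it must be wide enough to keep genuine same-species
matches (which differ by mutation load, not by halves) and narrow enough to
discard the sharply weaker homologous matches it exists to remove.

## Profiling

Reads are assigned to all their matched references, with the best-coverage
chunk per (read, reference) used for chunk bookkeeping. A read is *uniquely
matched* when all its candidate references belong to one species; matches
to several genomes of the same species do not break uniqueness.
High-confidence means k-mer coverage ≥ 0.75. Matched bases of a read
against a reference are approximated as `coverage × read length`.

Per reference the profiler tracks: read counts (total / unique /
high-confidence unique), the fraction of chunks holding at least one read,
per-chunk matched-base depths, and the similarity score — the nearest-rank
90th percentile of coverage over uniquely matched reads. Chunk depths are
normalized by their mean over *covered* chunks before taking the standard
deviation; this makes the depth-evenness threshold (default 2) scale-free,
which is the only reading under which a single default can serve genomes
at any abundance. Both "covered chunks only" and the denominator were open
choices; they are documented here as the package's definition.

The three rounds:

1. Loose pass: ≥ 1 uniquely matched read, ≥ 1 high-confidence uniquely
   matched read, chunk fraction ≥ 0.8, ≥ 50 matched reads.
2. Reads are reassigned among survivors (a read's candidate set shrinks,
   so uniqueness can only grow); thresholds tighten to ≥ 20 unique and ≥ 5
   high-confidence unique reads, and two criteria are added: relative
   chunk-depth standard deviation ≤ 2 and high-confidence proportion
   ≥ 10 % of unique reads. A two-stage assignment pass then ranks
   survivors by unique reads and removes, weakest first, any reference
   whose multi-mapped reads are all explainable by a strictly
   higher-ranked survivor and which lacks enough unique reads of its own.
   This rule is an approximation capturing the stated purpose of its
   antecedent (removing references that exist only as shadows of better
   ones); the original algorithm is external and not specified in detail.
3. Reads whose references were all removed are excluded; the round-2
   criteria (minus the two-stage pass) run once more.

Filtering is monotone by construction — later rounds filter the previous
round's survivors — and the tests assert it on every fixture run.

### Mode presets

Six presets (0 = pathogen detection … 5 = higher precision) scale these
thresholds. Mode 0 and mode 3 (default) are fixed by their documented
values — mode 0 requires only 2 of 10 chunks covered with one read each,
accepts a single unique read, disables the high-confidence proportion
floor, and switches the main-matches filter on. The intermediate and
stricter presets interpolate/extrapolate monotonically around those two
anchors; their exact values are package choices (no authoritative table is
available) and are visible in `chunkprof.profiler.MODE_PRESETS`.

### EM abundance estimation

Initialization splits each multi-mapped read's matched bases equally across
its candidates; a reference's abundance is its assigned base mass divided
by its genome size, normalized to sum 1 (sequence abundance; no separate
taxonomic-abundance variant is reported). Each iteration reassigns
multi-mapped mass proportionally to the previous abundances and stops after
10 iterations or when the predominant reference's abundance changes by
less than 1 % relative; if two references tie for predominant, the shared
maximum value is what is tested. Each read's fractional weights must sum
to one at every iteration; the implementation raises if conservation is
violated, and the tests record the full history.

Reports: a TSV sorted by (score, chunk fraction, abundance) descending —
so a low-depth pathogen with near-exact matches outranks an abundant
mediocre contaminant — and a CAMI profile (`@SampleID`/`@Version`/`@Ranks`
header; TAXID/RANK/TAXPATH/TAXPATHSN/PERCENTAGE rows) whose percentages
sum to 100 per rank. Abundance aggregation to a rank renormalizes over the
references that have an ancestor at that rank.

## Synthetic data

The generator produces uniform-ACGT genomes, a minimal four-file taxdump
(root → superkingdom → genera → species), and reads drawn multinomially by
target proportion at uniform positions on a uniformly random strand.
Sequencing error is substitution-only at rate `1 − identity` (a substituted
base always changes); there are no indels, no quality model, no GC bias,
no repeats and no shared ancestry between genomes unless constructed
explicitly. Consequences worth keeping in mind: real genomes' repeat
content and inter-species homology make uniquely matched reads scarcer
than in these fixtures, and indel-containing reads lose more k-mers than
the substitution model predicts. Passing tests demonstrate the machinery
(no false negatives, calibrated FPR, correct bookkeeping, abundance
recovery under the stated error model) — not field accuracy on real
communities.

The standard validation community is five 200-kb genomes at proportions
(0.4, 0.3, 0.15, 0.1, 0.05) with 20 000 error-free 150-bp reads, plus a
decoy reference sharing the first 20 % of genome 1 and receiving no reads
of its own; the decoy attracts multi-mapped reads but no unique ones and
must fall to round-1 criterion (i). These sizes run the full pipeline in
well under a minute while leaving multinomial noise (L1 ≈ 0.01) far below
the 0.05 recovery tolerance. At identity 0.95 and k = 21 the expected
surviving-k-mer fraction is 0.95²¹ ≈ 0.34, so the median read sits below
the 0.55 threshold — the sensitivity boundary the defaults imply — and a
test pins that behaviour.

## Numerical and edge-case notes

* Bloom counts are one-sided: counts ≥ exact intersection always, equality
  for every inserted k-mer. Exact count agreement for a random 150-bp
  query against a column it does not occur in is `(1−f_c)^ℓ` per pair —
  about 87.8 % at `f = 0.001`, ℓ = 130 — so per-pair equality rates
  meaningfully above that require a far smaller `f` (≤ ~8×10⁻⁵ for 99 %).
  The index cannot beat this bound; only the count's one-sidedness is
  guaranteed.
* Containers and index blocks are binary files with magic strings,
  versions and length checks; truncation raises a corruption error rather
  than yielding silently wrong counts. Search TSVs carry a `# k=… hash=…`
  comment header, and `merge` refuses tables whose k or hash disagree.
* The search TSV appends the reference genome length (`tLen`) to the hit
  rows: the profiler's depth and EM normalizations need it and the merged
  table is the profiler's only sequence-derived input.
* Degenerate inputs: reads shorter than k produce no hits (not an error);
  an all-blacklisted FASTA is an error; an empty hit table profiles to an
  empty report; references missing from the TaxId map are a hard error
  naming the offenders.

## Known limitations

Substitution-only read model; approximate matched-bases accounting
(`coverage × length` rather than per-base alignment); the two-stage
assignment rule is a simplified reconstruction; mode presets 1, 2, 4, 5
are package-chosen interpolations; no host-read removal, no strain-level
deconvolution, and no external-benchmark metrics are computed anywhere in
the package.
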