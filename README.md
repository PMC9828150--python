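# chunkprof

A k-mer-based taxonomic profiler for shotgun metagenomes that combines
sequence similarity with **genome-chunk coverage** evidence. It is aimed at
microbiome researchers who need accurate species-level profiles of
prokaryotic *and* viral communities, and at clinical users who need
confident pathogen calls from very low-depth samples (a handful of reads).

## How it works

**Indexing.** Each reference genome (plasmid sequences filtered by name) is
split into `n = 10` equal-size chunks with 150-bp overlaps; contigs are
first joined with `k−1` `N` spacers so no artificial k-mers appear. All
distinct canonical 21-mers of each chunk are hashed to 64-bit integers and
stored in a bit-sliced Bloom-filter block index (BIGSI/COBS family): chunks
are sorted by k-mer count, grouped into blocks of ≤ N columns, and each
block holds an `m × ⌈N/8⌉` bit matrix whose row *r* contains bit *r* of
every column's Bloom filter — one row lookup tests a k-mer against all
chunks of a block at once. `m` is sized from the block's largest chunk at a
false-positive rate `f = 0.3` with one hash function.

**Pseudo-mapping.** A read's distinct canonical k-mers (pooled across mates
for paired data) are tested against every chunk. The score is the *k-mer
coverage* `m/ℓ` — matched k-mers over the read's ℓ distinct k-mers — and
chunks with coverage ≥ `t = 0.55` (≈ 96.5 % identity) are reported. Although
`f = 0.3` is high per k-mer, the chance that an absent chunk reaches the
threshold is the binomial tail `P(X > m), X ~ Bin(ℓ, f)`, e.g. `5.3 × 10⁻¹⁰`
for a 150-bp read with 72 of 130 k-mers matched. Hits carry no taxonomy, so
results from searches against separate databases merge losslessly.

**Profiling.** Reads are assigned to matched references and a three-round
filter removes suspicious genomes using (i) uniquely matched reads,
(ii) high-confidence (coverage ≥ 0.75) uniquely matched reads, (iii) the
fraction of genome chunks covered, (iv) matched-read counts, (v) the
standard deviation of relative chunk depths and (vi) the high-confidence
proportion, with reads reassigned between rounds. Relative abundances of
the survivors are then estimated by EM: multi-mapped read mass is split in
proportion to current genome-size-normalized abundances and re-estimated
(≤ 10 iterations or < 1 % change of the predominant genome). Reports come
as a TSV sorted by similarity score / chunk fraction / abundance and as a
CAMI profile file.

## Worked example

Everything below runs offline on a simulated community:

```bash
chunkprof simulate --out-dir work/sim --n-genomes 3 --genome-length 30000 \
    --n-reads 1500 --seed 7
chunkprof compute --in-dir work/sim/genomes --out-dir work/chunks
chunkprof index   --in-dir work/chunks --out-dir work/db
chunkprof search  work/sim/reads.fastq -d work/db -o work/hits.tsv.gz
chunkprof merge   work/hits.tsv.gz -o work/merged.tsv.gz
chunkprof profile work/merged.tsv.gz --taxid-map work/sim/taxid.map \
    --taxdump work/sim/taxdump -o work/profile.tsv --cami-report work/out.profile
```

`work/profile.tsv` then contains one row per detected reference:

```
reference  taxid  rank     taxname          lineage                          abundance  reads  uniq_reads  hic_uniq_reads  chunks_fraction  score
genome3    102    species  Genus1 species3  Bacteria;Genus1;Genus1 species3  34.133     512    512         512             1.0              1.0
genome1    100    species  Genus1 species1  Bacteria;Genus1;Genus1 species1  33.333     500    500         500             1.0              1.0
genome2    101    species  Genus1 species2  Bacteria;Genus1;Genus1 species2  32.533     488    488         488             1.0              1.0
```

`abundance` is the genome-size-normalized relative abundance in percent
(here ≈ ⅓ each, as simulated); `uniq_reads` counts reads whose matches all
fall in one species; `chunks_fraction = 1.0` means every genome chunk
received reads — the coverage-evenness evidence behind each call; `score`
is the 90th percentile of k-mer coverage over uniquely matched reads (1.0:
exact matches). `work/out.profile` holds the same result in CAMI format,
with percentages summing to 100 at every rank.

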