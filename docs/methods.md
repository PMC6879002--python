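# Methods

This note documents the generative model behind the simulator, the
reconstruction and evaluation procedures, the conventions and defaults the
package commits to, and what the synthetic data do and do not tell you
about real libraries.

## The generative model

A Linked-Read library is simulated in the order real data are produced.

**1. Diploid template.** A haploid reference is duplicated into two
haplotypes and diverged by SNVs only, so both haplotypes keep the reference
coordinate system (no indels, no structural variants). Inside user-supplied
high-confidence regions a supplied VCF call set is inserted with its own
genotypes (phased `1|0`/`0|1` pin the haplotype; unphased heterozygotes get
a fair-coin haplotype). Everywhere else — or everywhere, when no regions
are given — random SNVs are placed per base with probability
`lc_density / 1000` (default 1 SNV/kb in expectation) with zygosity
heterozygous : homozygous in `het_hom_ratio : 1` (default 2 : 1, i.e.
P(hom) = 1/3), the heterozygous haplotype a fair coin, and the alternate
allele uniform over the three non-reference bases. `N` reference bases are
never mutated. Placement is per-base Bernoulli rather than fixed-count, so
adjacent SNVs are allowed and counts fluctuate binomially. When calls are
supplied without confident regions, all calls are inserted and random SNVs
avoid the call positions.

**2. Shearing.** Each haplotype is copied whole and cut from position 0 by
successive exponential(μFL) lengths; the last piece of each contig is
truncated at the contig end and pieces shorter than `min_len` (default
1 kb) are discarded. Copies accumulate until each haplotype holds
(C_F / 2) × (haploid reference length) bases — C_F is accounted against the
*haploid* genome, with molecules split evenly between haplotypes — and
randomly chosen molecules are then dropped so the realized C_F sits within
1% of target. Truncate-and-filter is one of several defensible readings of
"shear into exponential pieces"; it keeps interior piece lengths exactly
memoryless (retained interior lengths minus `min_len` are exponential(μFL),
which the test suite checks by Kolmogorov–Smirnov). On a 1 Mb contig the
end-truncation (downward) and the `min_len` filter (upward) nearly cancel,
leaving the retained mean within ~2% of μFL.

**3. Partitioning.** Partition sizes are drawn Poisson(N_F/P) with zeros
redrawn — an empty droplet holds no molecules and is invisible — and the
pooled molecules are dealt into partitions without replacement in random
order, so the final partition may run short. Each partition receives a
unique random 16-mer barcode; uniqueness is what downstream logic needs,
so no vendor whitelist is bundled. A warning fires past 4.8 million
partitions, the practical barcode ceiling of downstream assemblers.

**4. Reads.** Per molecule of length L the pair count is
Poisson(C_R · L / g), where g is the *genomic* bases per pair: the forward
read donates its first 16 bases to the barcode and the next 7 to an `N`
spacer, so g = 2 · read_len − 23 (277 at 2 × 150 bp). A Poisson count
(rather than deterministic rounding) reflects the stochastic capture of
molecule sequence in the droplet; the capture chemistry itself is not
modeled beyond C_R. Inserts are round(Normal(500, 50)) bp — the short
Illumina fragment range — clamped to [2 · read_len, L]; start positions are
uniform; the reverse read is the reverse complement of the insert's far
end. Substitution errors are i.i.d. per base at `error_rate` (default 0);
quality strings are constant at Q = round(−10 log₁₀ max(error_rate, 10⁻⁴)).
Molecules shorter than one insert are skipped and counted, not an error.

Output is an R1/R2 (gzip) FASTQ pair plus a plain-text truth TSV with one
row per pair recording barcode, partition, molecule, haplotype and
coordinates — the alignment-free ground truth the inference module can
consume in place of a BAM.

## Molecule reconstruction and profiling

Placements (one per read pair, spanning leftmost mate start to rightmost
mate end) are grouped by (barcode, contig) and sorted by leftmost
coordinate. A molecule is terminated when the end-to-start gap between
consecutive pair spans exceeds 50 kb or the contig changes; the gap is
measured end-to-start (not start-to-start) because that is insensitive to
read length, and at pair granularity because pairs are the unit of barcoded
evidence. Filters run in order: chain termination, then per-molecule floors
(≥2 pairs and ≥2 kb), then removal of barcodes retaining fewer than 3
molecules. Reconstruction is invariant to input order.

Estimators: C_F = Σ molecule length / haploid reference length;
C_R = (pairs × g) / Σ molecule length; N_F/P = molecules per retained
barcode; μFL/WμFL from the molecule-length sample, with WμFL defined as
Σ L² / Σ L (the standard length-weighted mean).

Truth-TSV placements default to *template-haplotype* coordinates
(`contig_hap1` / `contig_hap2`), the simulator's native coordinate system;
`split_haplotypes=False` collapses both haplotypes onto the reference
coordinates, as alignment to a haploid reference would. SAM/BAM input takes
the barcode from the `BX` tag and skips (with counters) secondary and
supplementary records, unmapped reads or mates, duplicate-marked records,
and records without a tag; each pair is counted once, from its leftmost
mate, using the template length for the span.

Subsampling is barcode-aware: to a target C_R, each molecule keeps
round(C_R · L / g) of its pairs by uniform sampling without replacement
(capped at what it has); to a target C_F, whole molecules are dropped
uniformly at random until the coverage first falls to the target.

## Assembly evaluation

**Contigs and Nx.** Scaffolds are split into contigs at every maximal run
of ≥10 `N`; shorter runs stay inside contigs, and contigs record their
origin and offset so the scaffold can be reconstructed byte for byte. Nx is
the largest L such that pieces ≥ L hold ≥ x% of the total, computed by a
descending cumulative scan.

**NA50.** Queries are broken at alignment-detected misassembly signatures
before the N50 scan. Blocks below 500 bp or below a mapping-quality floor
are ignored; query-side overlaps keep the longer block. A breakpoint is
declared between consecutive query-sorted blocks when (a) the target
contigs differ, (b) the strands differ, or (c) the target-side and
query-side gaps disagree by more than 1 kb (an indel-like discordance);
the query is split at the query-side midpoints. These three criteria with
the 500 bp / 1 kb length floors for contigs / scaffolds are this package's
own concrete re-specification of the misassembly definitions used by
standard evaluation pipelines, which are not restated in any single
formula; unaligned queries contribute their full length unbroken, the
conservative choice. Breaking never changes total length, so NA50 ≤ N50.

**Diploid fraction.** The reference is cut into fixed windows (default
500 bp; partial terminal windows are not scored). A window is covered by an
assembly contig when that contig's merged alignment blocks span the whole
window (`min_cov_frac = 1.0`; relaxable). "Covered by two contigs" is read
as one per haplotype: *diploid* windows have ≥1 haplotype-1 and ≥1
haplotype-2 contig, *haploid* windows exactly one haplotype, and windows
covered only by unlabeled contigs count toward overall coverage alone
(class `excess`, reported with a warning). Haplotype labels come from FASTA
header suffixes (`/1`, `/2`, or `_hap1`/`_hap2`) because the assembler
graph structures that define haplotype pairs are assembler-internal.
Classification is invariant to contig order and to splitting any alignment
block at an interior point.

**Overlap and phase blocks.** The chance expectation for the k-way overlap
of diploid regions across assemblies of the same genome is the product of
the per-assembly diploid fractions (independence); the departure of the
observed overlap is tested with a 1-df goodness-of-fit χ² on
(observed, total − observed) windows versus (total·p, total·(1 − p)), with
a flag when an expected cell drops below 5. Window-level dependence is not
modeled, so the p-value is an approximation; the statistic, not the
p-value, is the primary output. Phase blocks are operationalized as maximal
runs of diploid windows and summarized by their N50 — a coordinate-space
proxy for assembler-reported phase blocks, adequate for comparing design
points on the same genome but not comparable to assembler-internal
phase-block lengths.

## The synthetic reference

`generate_reference` draws i.i.d. bases at a requested GC content (default
0.41 in the bundled pipelines, the human-like value) and can plant
non-overlapping copies of one fixed random repeat unit as a stand-in for an
interspersed repeat family, with the copies reported as an annotation. It
has no chromosome structure, no GC heterogeneity, no satellite arrays, and
one repeat family at most — so tests passing on it demonstrate the
*mechanics* of shearing, partitioning, inference and window bookkeeping,
not performance on real genomic repeat landscapes. Likewise the simulator
omits PCR duplicates, GC-coverage bias, barcode sequencing errors and
chimeric molecules; conclusions about those effects cannot be drawn from
these synthetic libraries.

## Scale effects (read this before profiling toy genomes)

Molecule reconstruction merges any two same-barcode molecules that land
within the 50 kb chaining gap on the same contig. The expected number of
such collisions per partition is roughly

```
E[K(K−1)] / 2 × P(same haplotype) × (2·μFL + 2·gap) / G
```

with K ~ Poisson(N_F/P) and G the per-haplotype genome length. On a human
genome (G ≈ 3 Gb) at N_F/P = 10 and μFL = 37 kb this is ~10⁻³ per
partition — negligible. On a 2 Mb toy genome it is ~2 per partition:
merging then deflates the recovered N_F/P, inflates the recovered μFL, and
leaves C_F mildly underestimated (the fixture's recovery report shows
exactly this pattern). Conversely, at small N_F/P the "<3 molecules per
partition" filter removes a large share of partitions (42% at N_F/P = 3)
and biases C_F low. Faithful parameter recovery on synthetic data therefore
needs G ≫ N_F/P × (2·μFL + 100 kb); tens of megabases or more at the
standard N_F/P = 10. The package keeps the published filter thresholds
rather than rescaling them, because the thresholds are part of the
procedure being modeled.

## Defaults and numerical choices

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `read_len` | 150 | bp | standard high-throughput paired-end read length |
| `barcode_len` / `n_spacer` | 16 / 7 | bases | the Linked-Read forward-read layout |
| g (genomic bases/pair) | 277 | bases | 2·150 − 23; barcode and spacer carry no genomic information |
| `mu_fl` | 37 000 | bp | a mid-range molecule length for standard preparations |
| `n_fp` | 10 | molecules | the standard protocol's partition occupancy |
| `insert_mean` / `insert_sd` | 500 / 50 | bp | short-fragment insert range |
| `error_rate` | 0.0 | per base | clean-data default; 0.01 models a uniform 1% error |
| `lc_density` | 1.0 | SNV/kb | random-SNV density outside confident regions |
| `het_hom_ratio` | 2.0 | — | heterozygous : homozygous SNV ratio |
| shearing `min_len` | 1000 | bp | below this, molecules carry almost no linked information |
| inference `gap_kb` / `min_pairs` / `min_len_kb` / `min_frags_per_partition` | 50 / 2 / 2 / 3 | — | the published molecule-reconstruction filters |
| `max_gap_bp` / `min_block_bp` | 1000 / 500 | bp | misassembly gap-discordance and block floors |
| `window` / `min_cov_frac` | 500 / 1.0 | bp / — | diploid-fraction window size; full-span coverage |

Reproducibility: every pipeline stage draws from its own NumPy generator,
seeded by SHA-256 of `"{master_seed}:{stage_name}"` reduced below 2³¹, so
changing one stage's parameters does not perturb another's draws; identical
config + seed gives byte-identical outputs and manifests. The coverage
identity is enforced to 10⁻⁹ relative when all three of C, C_F, C_R are
supplied. Nx resolves the cumulative-sum threshold with a 10⁻⁹ guard so
exact-boundary ties take the longer piece. Degenerate inputs raise typed
errors (`EmptyInputError`, `InvalidParameterError`, `ConsistencyError`,
`DegenerateLibraryError`) rather than returning sentinel values, except the
empty library profile, which is a marked empty object.

## Problem sizes used by the test and acceptance runs

The suites run on synthetic genomes of 100 kb–2 Mb: template statistics
pool twenty to fifty 1 Mb genomes; the end-to-end recovery checks use 2 Mb
libraries of ~10⁴ molecules and ~3 × 10⁵ read pairs; evaluation operates on
toy assemblies of known construction, where the diploid fraction is checked
against its designed value exactly. These sizes exercise every code path at
desk scale; absolute performance numbers from real terabyte-scale libraries
(assembler N50s, genome-wide diploid fractions) are outside what synthetic
runs of this size can reproduce.

## Known limitations

* SNV-only diploid divergence: no indels or SVs in the template.
* No PCR-duplicate, GC-bias, barcode-error or chimeric-molecule models.
* The χ² overlap test treats windows as independent; its p-value is
  approximate.
* Phase blocks are diploid-run proxies, not assembler phase blocks.
* Parameter recovery on genomes ≲ 10 Mb is distorted by molecule-chaining
  collisions and partition-filter losses, as quantified above.
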