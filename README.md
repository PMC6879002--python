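# lrkit

Linked-Read library simulation, molecule reconstruction, and diploid-assembly
evaluation — a toolkit for exploring the parameter space of barcoded
(10x-Chromium-style) Linked-Read sequencing before committing to a library
preparation.

## The problem

Linked-Read sequencing partitions long DNA molecules into millions of
barcoded droplets and sequences each molecule shallowly with short paired-end
reads, so long-range information survives at short-read cost. The design of
such an experiment is governed by a small set of interdependent parameters:

* **C** — total sequence coverage of the genome,
* **C_F** — physical coverage: summed molecule length per haploid genome length,
* **C_R** — mean read coverage within one molecule,
* **N_F/P** — mean number of molecules sharing one barcoded partition,
* **μFL** — mean molecule length; **WμFL** — the length-weighted mean,
  Σ L² / Σ L (for exponentially distributed lengths, WμFL → 2 μFL).

They obey the identity **C = C_F × C_R**: every position is touched by C_F
molecules on average and each molecule is read to depth C_R. Assembly and
phasing quality depend on where a library sits in this space, so being able
to generate a library at an exact design point, to *measure* where an
existing library sits, and to subsample it onto a matched design point are
the three operations this package provides, along with the evaluation
metrics used to judge the resulting diploid assemblies (N50/NA50 with
alignment-based misassembly breaking, and the fraction of the genome
assembled in a diploid state on 500-bp windows).

## What is in the box

| module | what it does |
| --- | --- |
| `lrkit.params` | coverage identity, fragment-length statistics, design-point validation, flat config files |
| `lrkit.template` | synthetic reference genomes; diploid templates (two haplotypes + SNV table) from a VCF inside confident regions and random SNVs (1/kb, 2:1 het:hom) elsewhere |
| `lrkit.simulate` | exponential shearing to target C_F, Poisson(N_F/P) partition allocation with unique 16-base barcodes, paired-end reads at C_R with the barcode + 7-N spacer on every forward read; gzip FASTQ + a truth TSV sidecar |
| `lrkit.infer` | molecule reconstruction from barcode-grouped read placements (50 kb chaining gap, ≥2 pairs, ≥2 kb, partitions with <3 molecules removed), library profiling (estimated C_F, C_R, N_F/P, μFL, WμFL), and barcode-aware subsampling to a target C_R and/or C_F |
| `lrkit.asm_eval` | scaffold→contig decomposition at ≥10-N runs, N50/NA50, diploid/haploid window classification, multi-assembly overlap with chance expectation and a χ² test, phase-block N50 |
| `lrkit.cli` | the `lrk` command: `simulate`, `profile`, `subsample`, `evaluate`, `overlap`, `fixture` |

Placements for `profile`/`subsample` come from either a coordinate-sorted
SAM/BAM with `BX` barcode tags or the simulator's own truth TSV.

## Worked example

Run the bundled end-to-end pipeline on a 2 Mb synthetic genome — reference,
diploid template, simulated library at C_F = 200×, C_R = 0.2×, μFL = 37 kb,
N_F/P = 10, then molecule reconstruction from the truth sidecar:

```bash
lrk fixture --scale small --seed 7 --out fx
```

```json
{
  "n_inferred_fragments": 7821,
  "n_true_fragments": 10504,
  "realized": { "c": 40.009326, "c_f": 200.0000665 },
  "recovered": {
    "c_f": 189.6693745,
    "c_r": 0.20983910873813738,
    "mu_fl": 48502.589055108045,
    "n_fp": 7.505758157389636
  },
  "relative_error": { "c_f": 0.05165312749999998 },
  "requested": { "c_f": 200.0, "c_r": 0.2, "mu_fl": 37000.0, "n_fp": 10.0 }
}
```

Reading the numbers: the simulator hit the requested physical coverage
exactly (`realized.c_f` = 200.0) and the realized total coverage is
C = C_F × C_R ≈ 40×. Reconstruction recovers C_F within ~5% and C_R within
~5%; the recovered μFL is high and N_F/P low because on a 2 Mb toy genome
distinct molecules of the same partition often land within the 50 kb
chaining distance and are merged — a scale artifact of small genomes, not
of the method (see `docs/methods.md`, "Scale effects"). On real-genome
scales the collision rate is negligible.

The same steps are available separately:

```bash
lrk simulate --ref ref.fa --cf 100 --cr 0.2 --mufl 37000 --nfp 10 --seed 7 --out lib
lrk profile  --in lib_truth.tsv --ref-len 500000 --out prof
lrk subsample --in lib_truth.tsv --cr 0.1 --ref-len 500000 --seed 7 \
    --fastq-prefix lib --out sub
lrk evaluate --asm assembly.fa --paf aln.paf --ref-lens ref.fa --out eval
lrk overlap --fractions 0.589,0.733,0.772
```

The last command prints the chance expectation for a three-way overlap of
diploid regions under independence — the product of the fractions:

```json
{
  "fractions": [0.589, 0.733, 0.772],
  "chance_overlap": 0.333300964,
  "chance_overlap_percent": 33.330096399999995
}
```

## Scope

The toolkit generates and evaluates the *inputs and outputs* of a
Linked-Read assembly experiment; it does not run an assembler, an aligner,
or variant callers — assemblies come in as FASTA (haplotype labels in the
headers), alignments as PAF, variants as VCF. The simulator models SNV-only
diploid divergence, uniform substitution errors and stochastic molecule
capture; it does not model PCR duplicates, GC bias, barcode errors, or
quality-score profiles (`docs/methods.md` lists the full set of
assumptions and limitations).
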