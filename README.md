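# cpgdecon

Single-CpG-resolution analysis of MeDIP-seq data. A MeDIP-seq read is pulled
down because *some* methylated CpG it covers was bound by the antibody — but
which one is unobserved whenever the read covers several sites. `cpgdecon`
resolves that ambiguity with two latent-variable models fitted by EM, turns
the fitted contribution probabilities into integer per-site read counts, and
tests those counts for differential methylation between two samples.

## What it does

1. **Site discovery & segmentation** (`genome_io`): scan a reference FASTA
   (or a precomputed table) for CpG dinucleotides, drop blacklisted sites,
   and chain neighbors closer than the linking distance (default: max read
   length) into regions that can be analyzed independently.
2. **Coverage matrices** (`genome_io`): per region, record which consecutive
   CpG sites each mapped read covers (reads covering no site are discarded
   and tallied). MRE-seq reads are counted directly at their cut-site CpG.
3. **Allocation models** (`model_core`):
   - *single-contributor* — exactly one covered site caused the pulldown;
     conditioning independent per-site indicators on a row sum of 1 gives a
     multinomial law; EM maximizes the observed-span likelihood and
     allocates `[n·p_j]` reads per site (largest-remainder rounding, counts
     sum to n exactly).
   - *at-least-one contributor* — conditioning on a row sum ≥ 1 gives a
     truncated product-Bernoulli law; the corresponding EM updates are
     applied as printed, with degenerate all-zero collapses detected and
     flagged; allocation is `[n·q_j / (1 − ∏(1−q_s))]`.
   - a *raw* comparator credits each read to every site it covers.
4. **Differential testing** (`diff_test`): per-site two-sided Fisher exact
   test of allocated count vs library total between samples (pluggable
   statistic registry), Benjamini–Hochberg q-values, cutoff reports, and a
   replicate-null calibration harness.
5. **Simulation** (`simulate`): generative MeDIP/MRE read simulator (random
   breakage, capture iff a methylated CpG is covered, configurable
   contributor law and placement scheme, shared-truth replicate pairs) so
   the whole pipeline is testable without external data.

## CLI

```bash
# locate CpG sites and segment regions
cpgdecon sites --fasta ref.fa --link-dist 50 --blacklist bl.bed -o sites.tsv

# per-region coverage matrices (TSV dump)
cpgdecon matrix --reads reads.bed --sites sites.tsv -o matrix.tsv

# fit a model and allocate reads to sites
cpgdecon allocate --reads reads_A.bed --sites sites.tsv \
    --model multinomial --mre mre_A.bed -o counts_A.tsv

# per-site differential test between two count tables
cpgdecon test --a counts_A.tsv --b counts_B.tsv --method fisher \
    -o table.tsv --report cutoffs.tsv

# simulate a shared-truth replicate pair (reads, CpG map, MRE reads, truth)
cpgdecon simulate --seed 7 --outdir sim/

# full pipeline from a TOML config
cpgdecon run --config pipeline.toml
```

A minimal `pipeline.toml`:

```toml
reads_a = "reads_A.bed"
reads_b = "reads_B.bed"
cpg_table = "sites.tsv"   # or: reference = "ref.fa"
out_dir = "out"
model = "multinomial"
cutoffs = [1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8]
seed = 7
```

Outputs are TSV with a version/config header and no timestamps, so fixed
inputs and seed give byte-identical files. All coordinates are 0-based
half-open (BED convention); CpG sites are reported at the forward-strand C.

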