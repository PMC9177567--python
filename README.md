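# svpangut

Structural-variation (SV) analysis for gut-microbiome metagenome-assembled
genomes (MAGs), built for method development and validation on synthetic
data with planted truth.

Long-read (ONT) metagenomics resolves a class of genetic variation that
short-read pipelines miss: large insertions, deletions, and inversions
between same-species bacterial genomes from different people. These SVs are
highly distinct between individuals yet stable within one individual over
time — a gut-microbiome *fingerprint* — and they stratify a species into
strains whose associations with metabolites and host phenotypes differ.
`svpangut` implements that analysis chain as a tested, reusable library and
CLI:

- **`synthio`** — synthetic genomes, planted SVs with a bimodal length
  distribution (peaks at 140–160 bp and 1050–1150 bp), ONT-like long reads
  (mean 5683 bp), SV presence profiles, and cohort matrices in which chosen
  bacteria–metabolite correlations hold only in the SV-absent (SV0) strain.
  Every generator is deterministic in its seed and returns full truth
  records.
- **`magqc`** — MAG quality: N50, the representative-selection score
  `score = completeness − 5·contamination + 0.5·log10(N50)`, the QC filter
  (completeness > 70%, contamination < 10%), coding density.
- **`svcall`** — pairwise SV calling from collinear alignment blocks
  (built-in exact k-mer anchor/chaining aligner, or external alignments via
  PAF), with the contig-end filter (breakpoints within 10 bp of a contig
  terminus are flagged), per-Mb rate normalisation, and long-read spanning
  validation (a call is supported when ≥ 2 reads cover its breakpoints plus
  100 bp flanks on the allele-carrying genome).
- **`fingerprint`** — inter- vs intra-individual SV-rate comparison
  (two-sided Wilcoxon rank-sum), Jaccard distances on presence/absence
  repertoires, classical-scaling PCoA, and Procrustes with a permutation
  test (protest, 999 permutations).
- **`assoc`** — the SV-stratified association cascade: occurrence filters
  (species ≥ 50%, SV genotype groups ≥ 20% of present-samples, metabolites
  > 90% non-missing), Spearman screening with Benjamini–Hochberg FDR
  (q < 0.1), SV0/SV1 strain dissection (confounded ⇔ p_SV0 < 0.05 and
  p_SV1 > 0.05), and covariate-controlled partial Spearman.
- **`enrich`** — Fisher's exact enrichment of SV-affected genes (gene body
  containing an SV breakpoint) against all annotated genes, grouped by
  pathway, BH-adjusted.

## Worked example

Simulate a 200 kb bacterial genome, plant 30 SVs, call them back, and
validate the calls with error-free long reads from both genomes:

```sh
svpangut simulate genome --out ref.fasta --length-bp 200000 --seed 11
svpangut simulate svs --reference ref.fasta --out query.fasta \
    --truth-out truth.json --n-svs 30 --seed 12
svpangut call --reference ref.fasta --query query.fasta --out svs.tsv
# 30 retained calls (150.00 per Mb)

svpangut simulate reads --genome query.fasta --out reads_q.fastq --depth 10 --seed 13
svpangut simulate reads --genome ref.fasta  --out reads_r.fastq --depth 10 --seed 14
cat reads_q.fastq reads_r.fastq > reads.fastq
svpangut validate --sv-table svs.tsv --reads reads.fastq \
    --reference ref.fasta --query query.fasta --out validation.tsv
# supported fraction: 1.0000
```

All 30 planted SVs are recovered (`svs.tsv`, 1-based coordinates; the
third call below is a large insertion, > 500 bp):

```
sv_id     sv_type    ref_contig  ref_start  ref_end  length_bp  is_large
sv_00006  insertion  contig_1    11629      11628    160        False
sv_00007  deletion   contig_1    12519      12667    149        False
sv_00008  insertion  contig_1    13815      13814    1052       True
```

and every call is spanned by reads on both genomes (`validation.tsv`):

```
sv_id     supporting_reads_ref  supporting_reads_query  supported
sv_00006  14                    13                      True
sv_00007  16                    15                      True
sv_00008  8                     6                       True
```

The `rate_per_mb` printed by `svpangut call` (150 SVs/Mb here, a dense test
genome) is the quantity compared between individuals: on default cohort
profiles the median inter-individual rate is ~16–18 SVs/Mb against a median
of 0 within an individual.

The association cascade runs the same way from TSV matrices:

```sh
svpangut simulate cohort --out-dir cohort/ --seed 5
svpangut assoc --cohort-dir cohort/ --out-dir assoc_out/
# 4 confounded (species, KO, target) records
```

`assoc_out/associations.tsv` lists, per (species, KO, metabolite), the
all-sample Spearman rho/p/q and the SV0/SV1 subgroup statistics with the
final verdict.

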