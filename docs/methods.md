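# Methods

This note documents the models, parameter choices, and numerical decisions
behind `svpangut`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Synthetic genomes and planted SVs

Reference genomes are i.i.d. base sequences at a configurable GC fraction
(default 0.45, typical of gut commensals), split into equal-length contigs.
Planted SVs are drawn from a two-component length mixture — uniform peaks on
140–160 bp and 1050–1150 bp with equal weight, plus an optional log-uniform
tail (weight 0 by default) — reflecting the bimodal SV length distributions
seen in gut-microbiome assemblies, where the short mode tracks
mobile-element activity. The mixture is phenomenological, not a mechanistic
claim. The default type mix is 0.45 insertion / 0.45 deletion / 0.10
inversion: real cohorts show insertions ≈ deletions with inversions three
orders of magnitude rarer, but a faithful inversion rate would leave a
200-SV benchmark with no inversions to score, so inversions are
over-represented at a rate that still keeps them the rare class. Inversion
lengths come from the long component only (observed inversions are all
> 500 bp) with a 50 bp floor.

Placement is rejection sampling (cap 1000 retries) with a minimum inter-SV
gap of 200 bp (2× the default validation flank) and a 200 bp default
keep-out from contig ends; runs feeding read validation use a 3 kb keep-out
instead, because reads truncate at contig ends (MAG contigs are linear, no
circularity), so spanning coverage is undefined within roughly half a read
length of a terminus. Inserted sequence is random at the genome's GC and
rejected if it shares any 21-mer with the ±100 bp flanks, so placement is
unambiguous for an exact-k-mer aligner. Coordinates are 0-based half-open
internally; exported tables are 1-based inclusive.

The truth list records reference and query coordinates for every event;
re-applying it to the reference reproduces the query byte-for-byte (tested
with an independent re-applier).

## Long reads

Read lengths are log-normal with mean 5683 bp (σ_log = 0.55, floor 200 bp),
the scale of size-selected ONT fecal libraries. Errors are i.i.d. per-base
substitutions/insertions/deletions (each rate ≤ 0.2, default 0); quality is
flat. No chimeras, no strand bias, no quality-score realism — the model is
sufficient for spanning-coverage arithmetic, which is what validation
tests, and nothing else.

## Anchor aligner and SV typing

The built-in aligner indexes k-mers (default k = 21) unique in both
genomes, anchors query positions on both strands, and chains anchors that
preserve strand, reference contig, and diagonal into collinear blocks
(blocks < 100 bp are dropped). Between consecutive blocks, a reference gap
exceeding the query gap by ≥ 50 bp is a deletion, the converse an
insertion; near-balanced gaps are not typed (substitution-like breaks). A
'−'-strand block flanked by '+' blocks is an inversion; terminal strand
flips are flagged, not typed. Blocks may micro-overlap by up to 25 bp where
sequence coincides across a breakpoint; gap differences, and therefore call
lengths, are exact under such symmetric trims. Calls with a breakpoint
closer than 10 bp (strict) to any contig terminus of either genome are kept
but flagged `contig_end`, for auditability rather than silent dropping.

This aligner is desk-scale plumbing: exact matching on unique k-mers is
enough for clean or lightly mutated genomes and for mapping error-free to
low-error reads, and it is what the tests exercise. For real, divergent
genomes the PAF import path is the intended route; re-implementing a
seed-and-extend whole-genome aligner is out of scope.

Read mapping for validation uses the same unique-k-mer index, taking the
densest consistent-diagonal anchor cluster per read (diagonal tolerance
50 bp). An optional anchor stride (default 1) trades interval precision
(< stride bp per end, by bounded extrapolation) for speed on deep read
sets; the acceptance run uses stride 5 against ±100 bp flank windows.

A deletion's material lives on the reference, an insertion's on the query,
so support is counted on the allele-carrying genome (both for inversions):
a read supports a call when its mapped interval covers breakpoints ± flank
(100 bp), and a call is supported at ≥ 2 such reads.

## Fingerprint statistics

Per-sample SV profiles are Bernoulli carriage over a shared pool
(default: 100 pool SVs, carriage 0.211, 2 Mb genome), chosen so the
expected inter-individual pairwise difference is 2·p·(1−p)·pool ≈ 33 SVs
≈ 16.7 per Mb, the scale reported for cross-sectional gut cohorts; repeat
samples of one individual copy its profile exactly by default
(within-individual stability). Rates are compared by Mann–Whitney U with
midranks: exact enumeration when the combined n ≤ 12 with no ties,
otherwise the normal approximation with tie and continuity corrections
(scipy's implementation behind the module surface).

Jaccard distances define two samples with empty repertoires as distance 0
(identical emptiness; configurable to NA). PCoA is classical scaling with
explicit semantics: negative eigenvalues (non-Euclidean input) are dropped
with a warning and k is reduced to the positive-eigenvalue count;
coordinates are centred by construction. protest centres and unit-trace
scales both configurations, computes m² = 1 − (Σσᵢ)² from the singular
values of X′Y (the optimal rotation's residual), correlation = √(1 − m²),
and permutes the row order of the second configuration:
p = (1 + #{m²_perm ≤ m²_obs}) / (n_perm + 1), so the smallest attainable p
at 999 permutations is exactly 0.001. Coupled repertoire matrices for
testing draw samples from four latent community types (10%
individualisation) with the second matrix a 2% bit-flipped copy of the
first; the group structure mirrors clustered real repertoires and gives the
ordination dominant, stable axes.

## Cohort generator and association cascade

Species presence is Bernoulli (default occurrence 0.95 — headline species
in the motivating cohorts are genotyped in essentially every sample);
abundance is log-normal where present, 0 otherwise; the SV-genotype matrix
(columns `species:KO`) is Bernoulli 0.5 where the species is present and NA
exactly where it is absent. For each planted confounded triple (species,
KO, metabolite), the metabolite's latent normal tracks log-abundance
through a Gaussian copula with Pearson r = 2·sin(π·ρ/6) among present SV0
samples, giving Spearman ρ (default 0.7) there, and is independent noise
among SV1 samples — the strain-level confounding signature. Six additional
background pairs carry a direct, genotype-independent correlation
(Spearman ≈ 0.6) in all present samples: real screen families contain many
plain bacteria–metabolite associations, and step-up FDR power for the
planted pairs depends on how many true signals share the family.
Metabolite missingness is MCAR at 5%; the phenotype is a noisy negative
linear function of the planted metabolites' latents (a fasting-glucose-like
readout); covariates are age/sex/BMI noise.

The cascade applies the three occurrence rules in order (species ≥ 50% of
samples; both genotype groups ≥ 20% of the species' present-samples, the
denominator where genotype is defined; metabolites strictly > 90%
non-missing), logging every decision. Screening is midrank Spearman over
the species' present-samples with BH across the target block (one family
per block, mirroring separate fecal/serum/urine analyses); subgroup
p-values in the dissection are reported raw. Spearman p uses the
t-approximation except n ≤ 9, where the full permutation distribution is
enumerated; zero-variance inputs return NA with a warning. The partial
(covariate-controlled) correlation residualises midranks on the covariates
with an intercept, drops collinear columns with a warning, and uses
n − c − 2 degrees of freedom.

Two calibration facts shape expectations on synthetic and real data alike.
First, the all-sample correlation of a confounded pair is diluted to about
ρ_SV0/2 (the SV1 strain contributes none), so a q < 0.1 screen sits near
its power boundary at ρ_SV0 = 0.7 and n = 100 — roughly 80% of planted
pairs pass per run. Second, BH at FDR 0.1 *admits* about one false screen
discovery per family once ~9 true pairs are present, and a false-screened
pair dissects as "confounded" in some KO roughly 40% of the time; a
downstream consumer should treat KO-level verdicts on a pair as a set, not
as independent discoveries. Conditional on a planted pair passing the
screen, the dissection assigns the confounded verdict to the planted KO in
≈ 95% of replicates.

## Enrichment

A gene is SV-affected when its body interval contains a retained call's
ref_start or ref_end (gene-body only; bacterial TSS annotation is not
attempted). The contrast is foreground vs background-minus-foreground
(configurable to the full background); Fisher's conditional two-sided p
(tables at most as probable as observed), odds ratio ad/bc, BH across
pathways. Multi-pathway genes count in every mapped pathway. Zero-margin
tables return p = 1 with a warning. Note the two-sided Fisher p on discrete
tables is conservative: under a random foreground its distribution
stochastically dominates uniform, which is the calibrated (and tested)
behaviour.

## What the benchmarks do and do not show

Passing tests demonstrate the pipeline's arithmetic and inference on clean,
planted-truth data: exact coordinate bookkeeping, per-type recall/precision
≥ 0.95 at 1 Mb / 200 SVs, full spanning support with error-free 20× reads,
kernel agreement with enumeration oracles, and calibrated
null behaviour of the screen, dissection, enrichment, and protest stages.
They do not demonstrate robustness to assembly error, repeat-induced
misalignment, chimeric or high-error reads, compositionality of relative
abundances, or metabolite quantification noise — real-data performance
depends on the upstream assembler, binner, and aligner, which this package
deliberately does not re-implement.

Problem sizes in the test suite and acceptance script (1 Mb / 200 SVs for
caller scoring; 300 kb / 60 SVs / 20× for validation; 100–500 replicate
cohorts for calibration) were chosen as the smallest scales at which the
statistics of interest are stable.
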