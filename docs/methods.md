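# Methods

## Coordinate model

All internal coordinates are 0-based half-open; GFF3 (1-based closed) is
converted at the reader/writer boundary and BED is taken as-is, so no other
module ever performs an off-by-one adjustment. Genes are single,
pre-collapsed transcript models (one per gene id) with exons kept in
transcription order; the first intron is the gap between exons 1 and 2 in
that order. Which reference gene build to use, and how isoforms are
collapsed into it, is left to the annotation supplier — the pipeline takes
whatever single-model annotation it is given. Strand "." is legal for reads
(ChIP libraries are effectively unstranded here) and illegal for genes,
because TSS windows need an orientation.

## Peak signal ratio

The calling statistic for every library is a per-bin *signal ratio*.
Reads are counted into fixed bins (default 100 bp) by their midpoint; no
strand shift or fragment extension is applied. This midpoint rule is a
deliberate simplification relative to fragment-model callers: at the bin
size used, a fragment-size model changes bin counts by at most one bin of
displacement, and the ratio statistic is insensitive to it.

With an input (control) library the ratio in bin *b* is

    r_b = [(chip_b + p) / L_chip] / [(ctrl_b + p) / L_ctrl]

with pseudocount p = 1 read and L the mapped library sizes. Without a
control — the default, since the assay design provides none — the
denominator is a genome background density estimated from the ChIP track
itself by a Poisson-trimmed mean: starting from the plain mean count per
bin, bins above the 0.999 Poisson quantile of the current estimate are
excluded and the mean re-taken until stable. The trimming matters: truly
enriched bins inflate a plain genome-wide mean by the enriched fraction of
the library (≈ 25% at the simulation defaults), which would deflate every
ratio by the same factor and push genuine 10-fold enrichment below a
ratio-8 cutoff. The trimmed estimate recovers the background rate to ~1%
whenever enriched regions are a small fraction of the genome, which is the
regime this analysis assumes.

Peaks are maximal runs of bins with r ≥ t, merged across gaps ≤ 200 bp,
discarded below 100 bp width. The summit is the centre of the max-ratio
bin (leftmost on ties — a determinism rule, not a biological claim), and
it is the summit, not the region, that drives all gene assignment. Default
thresholds are t = 8 for Smad2/3 and H3K4me3 and t = 5 for H3K27me3;
windows are 10 kb upstream → end of first intron for binding-site
assignment (gene end for intronless genes; a `window_end=intron_start`
mode is provided because "first intron" can be read either way) and
±1 kb of the TSS, bounds inclusive, for mark status.

## Expression processing

Intensities emulate Affymetrix average-difference values: each array is
rescaled so its mean is exactly 100, probes are kept when some timepoint
strictly exceeds 70, and fold changes are ratios to the 0 h column with a
denominator floor ε = 1 (average-difference values can be ≈ 0 after
background subtraction; the floor keeps ratios finite without affecting
any expressed probe). *Up* and *down* are strict (> 2, < 0.5). Gene-level
values collapse to the probe with the highest mean intensity (ties broken
by probe id); probe-level tables are retained because category counts are
conventionally reported per probe. All orderings break ties by identifier
so every output is a deterministic function of the input.

## Enrichment statistics

The 2×2 statistic is Pearson's χ² without continuity correction (the
intended regime is hundreds-to-thousands of genes; a Yates flag exists),
with p from the upper tail of χ²(1). Fold enrichment is the set's
frequency inside the category over its frequency in the universe, which is
symmetric under set/category exchange. The enrichment universe is always
an explicit argument — annotated genes for chromatin questions, kept
(expressed) genes for expression questions — because the choice changes
the answer and should be visible in the call.

The GSEA enrichment score uses hit increments `|score|^p / Σ_hits |score|^p`
(default p = 1 on the fold-change scores) and miss decrements
`1/(N − N_h)`; the ES is the signed extremum of the running sum, with the
positive extremum preferred when the two magnitudes tie within 1e-12 (the
tie rule makes the streaming scan, the vectorised permutation kernel and
the brute-force oracle agree bitwise-stably). Significance comes from
gene-set (label) permutation: random same-size sets over the ranked
universe, p = (1 + #{|ES*| ≥ |ES|}) / (n_perm + 1). Label permutation is
the only scheme available to a one-array-per-timepoint design; phenotype
permutation would require replicate arrays that do not exist here. The
normalised-ES / FDR machinery for multi-set screens is out of scope.

Under the null (sets drawn independently of the ranking) the permutation
p-value is uniform on {1/(B+1), …, 1}, so the test's type-I error at
α = 0.05 with B = 999 is exactly 0.05; the acceptance suite measures this
over 2,000 replicates.

## Synthetic data

The generator's job is to realise a known truth with the statistical
structure the pipeline assumes: genes in named truth classes (Smad target
or not × promoter-state trajectory × expression response), ChIP reads as
uniform Poisson background plus planted in-peak enrichment at
(fold − 1) × background density, and lognormal expression with planted
multiplicative effects. The fully qualifying class (`nedd9_like`: target,
bivalent→K4-only, TGF-β ×3, RANKL ×0.3 by 72 h) is the canonical planted
positive for end-to-end tests. Sequenced totals are back-calculated so the
mapped fraction is ~71.7%, matching the library summary the pipeline
reports.

Default study conditions: 100 genes on 2 × 1.2 Mb chromosomes, ≥ 11 kb
intergenic gaps (so neighbouring 10 kb target windows cannot capture each
other's promoter peaks), background 0.05 reads/bp, enrichment fold 10,
50 bp reads, 2 probes/gene, lognormal noise σ = 0.25, 15% of probes
planted below the detection floor. Two geometry/depth choices deserve
justification:

- **Smad2/3 peaks sit 90% upstream of the TSS.** The target window ends at
  the first intron, which for a short first exon + intron can lie < 500 bp
  into the gene body; a peak centred on the TSS can then put its summit
  outside the window and make a planted positive unrecoverable by
  construction. Upstream placement keeps the whole peak inside the window
  for every gene geometry (and upstream/promoter-proximal binding is the
  expected location anyway). Mark peaks stay centred on the TSS, matching
  the symmetric ±1 kb rule.
- **Background 0.05 reads/bp.** At 100 bp bins this is λ = 5 per bin, at
  which a spurious single-bin mark call near a TSS (count reaching the
  K27 cutoff) has probability < 1e-4 per library, so the planted candidate
  set is recovered *exactly*, not just at high rate. At λ = 2 (0.02/bp)
  such calls occur in a fifth of runs and exact recovery is not a
  statistically sensible expectation; 0.02/bp is retained in the
  peak-recovery benchmark, whose overlap-based recall criterion tolerates
  it.

Per-class fractions default to 10% `nedd9_like`, 15% stable-bivalent and
15% constitutively active targets, 5% non-target resolving, 20/15/20%
non-target active/silent/background — so Smad targets are genuinely
enriched among resolving genes and TGF-β-up / RANKL-down genes, the
qualitative structure the enrichment stage is meant to detect. Every
random stream is seeded by stable hashing of (master seed, module, sample
labels), so adding a sample never perturbs existing ones and all outputs
are pure functions of (config, seed).

What the generator does **not** emulate — and what green tests therefore
do not certify on real data: mappability and GC bias, duplicate reads,
fragment-length effects, replicate variance, probe cross-hybridisation,
and any correlation between chromatin state and expression beyond the
planted class structure.

## Numerical and degenerate-input conventions

Empty ChIP track → all-zero ratios (never a division error); empty peak
list → no targets/marks; all-zero array column, zero-margin 2×2 table,
gene set empty or equal to the universe, unknown timepoint → explicit
errors naming the offender. ES is clipped to [−1, 1] against last-ulp
cumsum overshoot. An infinite calling threshold yields zero peaks, zero
targets and zero candidates without error, and candidate sets are
anti-monotone in every threshold.

## Scale of the shipped experiments

Tests and the acceptance script run the full pipeline on the default
synthetic study (100 genes, 2.4 Mb, ~120k reads/library, ~1–2 s per run)
and the peak benchmark on 1 Mb at 0.02 reads/bp; these sizes were chosen
as the smallest at which the Poisson and permutation statistics are in
their intended regimes, and all counts reported by the package scale with
the input, not with these defaults.

## Known limitations

No FDR-controlled peak calling or broad-domain segmentation; one model per
gene (no isoforms); no batch/replicate modelling in expression; the
candidate rule is a hard conjunction (no scoring or ranking of
candidates); the signal-ratio definition, while the simplest consistent
with a stated cutoff, is not calibrated against fragment-model callers.
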