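# bivalent-smad

An integrative ChIP-seq + expression pipeline for osteoclast biology: it
nominates **Smad2/3 target genes whose bivalent promoters resolve under
TGF-β and whose expression is TGF-β-induced and RANKL-repressed** in bone
marrow–derived macrophages (BMMs), the osteoclast precursor. The package is
aimed at epigenomics analysts who want the whole chain — signal-ratio peak
calling, promoter-state classification, time-course fold changes, and
enrichment statistics — as tested, reusable, deterministic components, plus
a synthetic-data generator that plants a known truth so every stage can be
validated end to end without external data.

## The analysis

Given aligned read intervals (BED6) for Smad2/3, H3K4me3 and H3K27me3 ChIP
libraries under TGF-β(+) and TGF-β(−) conditions, a gene annotation
(GFF3/BED12) and probe × timepoint expression matrices:

1. **Signal-ratio peaks.** Reads are binned (100 bp, midpoint rule) and a
   per-bin *peak signal ratio* is formed: library-normalised ChIP density
   over a reference density — an input library when present, otherwise a
   Poisson-trimmed genome background estimated from the ChIP track itself.
   Maximal runs of bins with ratio ≥ *t* (merged across ≤ 200 bp gaps) are
   peaks; Smad2/3 and H3K4me3 use *t* = 8, H3K27me3 uses *t* = 5. Each
   peak's summit is the centre of its max-ratio bin.
2. **Gene assignment.** A gene is a *Smad2/3 target* when a Smad2/3 summit
   falls in the strand-oriented window from 10 kb upstream of the TSS to
   the end of the first intron. A gene is K4(+)/K27(+) under a condition
   when a mark summit lies within ±1 kb of the TSS. Each gene gets a state
   in {K4+K27+, K4+K27−, K4−K27+, K4−K27−} per condition and a transition
   label; `K4+K27+->K4+K27-` is the bivalent-to-active resolution of
   interest.
3. **Expression.** Arrays are scaled to mean intensity 100; probes with
   max intensity > 70 at some timepoint are kept; fold changes are taken
   against 0 h (ε = 1 denominator floor), with *up* ⇔ ratio > 2 and
   *down* ⇔ ratio < 0.5, and ranked gene lists built at 24 h (TGF-β) or
   72 h (RANKL).
4. **Enrichment.** 2×2 fold enrichment
   `(a/(a+c)) / ((a+b)/N)` with Pearson χ² (df = 1, no continuity
   correction), and the GSEA running enrichment score
   (hit step `|s|^p / Σ|s|^p`, miss step `1/(N−N_h)`; ES = signed
   extremum) with a gene-set permutation p-value
   `(1 + #{|ES*| ≥ |ES|}) / (n_perm + 1)`.
5. **Candidates.** Default rule: Smad2/3 target ∧ bivalent→K4-only.
   Optional flags add TGF-β-up at 24 h and RANKL-down at any (or all) of
   24/48/72 h.

The synthetic generator plants genes in named truth classes (the fully
qualifying class is called `nedd9_like`), realises them as Poisson
background plus planted enrichment and as noisy expression time courses,
and writes everything as plain-text files with a `truth.json` for scoring.

## Worked example

```sh
bivalent-smad simulate --outdir demo --seed 7
cat > demo.yaml <<EOF
annotation: demo/annotation.gff3
sample_sheet: demo/samples.yaml
tgfb_expression: demo/expression_tgfb.tsv
rankl_expression: demo/expression_rankl.tsv
seed: 7
EOF
bivalent-smad -v run --config demo.yaml --outdir demo_out
```

prints (abridged):

```
INFO bivalent_smad: peaks[Smad2/3/TGFb_plus]: 40
INFO bivalent_smad: Smad2/3 target genes: 40 / 100
INFO bivalent_smad: bivalent->K4-only genes: 15
INFO bivalent_smad: TGFb expression: kept 109 probes (82 genes)
INFO bivalent_smad: GSEA TGFb: ES=0.760 p=0.000999
INFO bivalent_smad: GSEA RANKL: ES=-0.519 p=0.1079
INFO bivalent_smad: candidate genes: 10
10 candidate genes
gene_0014
...
gene_0095
```

Forty of the 100 simulated genes carry planted Smad2/3 binding and are all
recovered as targets; 15 genes have a planted (or planted-adjacent)
bivalent→K4-only transition; their intersection — the 10 `nedd9_like`
genes planted by the generator — is exactly the reported candidate set
(compare `demo/truth.json`). The positive TGF-β enrichment score says
targets concentrate at the top of the TGF-β-induced ranking; the negative
RANKL score says they sink toward the RANKL-repressed end.
`demo_out/` additionally contains per-sample peak BEDs, bedGraph tracks,
TSS metaprofiles, gene-state and fold-change tables, evidence per gene and
a machine-readable `report.json`.

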