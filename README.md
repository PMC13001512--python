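# g4chromatin

Copy-number-aware integrative analysis of G-quadruplex (G4) ChIP-seq,
ATAC-seq and RNA-seq data for two-condition (case vs control) studies —
the statistical toolkit behind questions like: *do changes in endogenous
G4 formation track changes in chromatin accessibility and gene
expression, and do the two chromatin signals act jointly on
transcription?*

It is written for computational biologists analyzing matched
peak/count/expression data from disease-vs-control or drug-vs-vehicle
designs (the motivating setting is a BLM-helicase-deficient "Bloom
syndrome-like" contrast, where genome instability makes copy-number
correction of chromatin counts essential), and for anyone who needs
permutation enrichment of genomic interval sets with honest nulls.

## What it computes

- **Copy-number normalization** — each peak is assigned the copy-number
  ratio CNR = 2^log2ratio of its overlapping (or closest) genomic segment;
  for CNR ≥ 1 case-sample counts are divided by CNR, for CNR < 1
  control-sample counts are multiplied by it, before any differential
  testing.
- **Differential testing** — a transparent negative-binomial stand-in for
  DESeq2/edgeR: median-of-ratios size factors (or loess MA-trend offsets),
  moderated method-of-moments dispersions (variance = μ + αμ²), per-feature
  Wald test of the condition effect, Benjamini–Hochberg adjustment, and
  up/down/nd status at p_adj < 0.05.
- **Permutation enrichment** — observed overlap of a query interval set
  with a subject set versus a null from genome shuffling (length-preserving,
  excluded-region aware) or universe resampling;
  z = (obs − mean₀)/sd₀, fold = obs/mean₀, add-one empirical
  p = (1 + #{null ≥ obs})/(1 + n_perm).
- **Strandedness inference** — unstranded G4 ChIP peaks are called
  Watson/Crick when they intersect strand-resolved in-vitro G4 hits on one
  strand only, then classified template ("transcribing") vs non-template
  relative to their promoter-linked gene.
- **Concordance quadrants** — two contrasts joined on a shared universe of
  N features; each signed quadrant (e.g. ++) tested against its
  hypergeometric expectation nK/N with enrichment tail P(X ≥ k) and
  depletion tail P(X ≤ k).
- **Tri-modal integration** — promoter linking (TSS ± 3 kb), TPM/RPKM and
  zFPKM-style activity calls (inactive below z = −3), cross-modal Pearson
  correlations of log2 fold changes, proximity-rank decay of the G4–ATAC
  coupling, additive stratification of expression change by
  (ATAC status × G4 status), and the type-III interaction ANOVA
  rna = atac + g4 + atac×g4 under sum-to-zero contrasts.
- **Synthetic study generator** — a fully seeded two-condition study
  (genome, genes, peaks, stranded hits, CNV segments, NB counts) with
  planted effect sizes, promoter enrichment, strands and copy-number
  ratios recorded as ground truth, so every stage above is validated by
  recovery.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

The `analysis/` scripts run the whole pipeline on a generated study and
write their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_cnv_normalize.py
python analysis/03_differential.py
python analysis/04_enrichment.py --seed 0
python analysis/05_strand.py
python analysis/06_concordance.py
python analysis/07_integrate.py
```

With seed 0 this prints, among other things:

```
  planted promoter enrichment fold: 12.72
atac: 742/5000 peaks in altered segments rescaled (0 assigned by proximity)
atac: 1205/5000 called differential (p_adj < 0.05); planted-effect bias -0.008, power 0.74, null leakage 0.042
G4 peaks in promoters: fold 12.82 (planted 12.72), z 111.6, empirical p 0.00332
950/1200 peaks strand-assigned (79.2%); 950/950 match the planted strand
  ++: 79 (52.7% of doubly-differential)   --: 71 (47.3%)
Pearson g4_vs_rna: r = 0.790 (p = 1.38e-181)
G4-ATAC coupling: r = 0.75 at overlap, max |r| = 0.07 at rank +/-1
```

Reading: the generator planted a 12.7-fold promoter enrichment of G4
peaks and the shuffle-null permutation estimate lands on 12.8; peaks
inside amplified/deleted segments are rescaled before testing, after
which the differential stage recovers planted log2 fold changes with
|bias| < 0.01; every strand call made matches the planted strand (peaks
without an in-vitro hit stay unassigned); the ATAC and G4 contrasts are
strongly sign-concordant over promoter-linked genes (no discordant
quadrant occupied); and the G4–ATAC fold-change coupling is confined to
directly overlapping peaks, vanishing at the first non-overlapping
neighbour — exactly the planted local-only structure.

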