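# Methods

`g4chromatin` implements the statistical core of an integrative
case/control epigenomics analysis: G-quadruplex (G4) ChIP-seq peaks,
ATAC-seq open-chromatin peaks and RNA-seq expression are compared between a
disease condition (e.g. a BLM-helicase-deficient cell line) and its
control, with copy-number-aware normalization, permutation-based interval
enrichment, G4 strandedness inference and tri-modal integration.  All of
it is exercised end to end on a synthetic study generator that plants
known effects, so every stage is validated by recovery of planted truth
rather than by comparison to a particular external tool.

## Coordinate conventions

Every interval is 0-based, half-open `[start, end)`.  BED files are read
and written natively in this convention; GTF (1-based inclusive) is
converted at the parser boundary.  The TSS of a "−"-strand gene is
`end − 1`, the last covered base, which is unambiguous under half-open
coordinates.  Strand is ignored in all overlap computations (G4 ChIP peaks
are unstranded); it only matters for promoter orientation and strandedness
calls.

## The synthetic study generator

`simulate.generate_study` composes independent sub-generators (genome,
genes, peaks/hits, copy-number segments, effect sizes, counts), each
consuming its own child random stream spawned from one top-level seed via
fixed `SeedSequence` spawn keys.  Adding a generator therefore never
perturbs the output of the others, and an identical `SimConfig` yields a
byte-identical study.

Default study conditions (all configurable on `SimConfig`):

| parameter | default | rationale |
| --- | --- | --- |
| genome | 4 × 25 Mb chromosomes | large enough that promoters cover ≪ 1 of the genome, desk-scale runtimes |
| excluded regions | 2% of each chromosome in ~50 kb blocks | gap/blacklist analogue for the shuffle null |
| genes | 1000, non-overlapping, 2–5 exons, ~50% per strand, 5–20 kb | rejection-sampled; each carries a CDS so UTRs exist |
| ATAC peaks | 5000; 90% of genes get a promoter peak covering the TSS (width ~log-normal, median 988 bp); the rest background (median 347 bp) | the two medians reproduce the reported widths of G4-overlapping vs G4-free open regions |
| G4 peaks | 1200, median width 300 bp; 80% placed covering gene TSSs | matches the reported ~80% promoter fraction of endogenous G4 peaks |
| G4-seq hits | one stranded hit inside 80% of G4 peaks (the reported in-vitro validation rate) plus 1000 background hits | drives strandedness inference |
| copy number | 10% of the genome amplified (log2 ratio +1), 5% deleted (−1), segments tiling each chromosome | a visible but not dominant CNV landscape |
| differential fractions | ATAC 0.3, G4 0.2, RNA 0.3 | between the reported per-modality differential fractions |
| effect sizes | sign ± at random, magnitude N(1.0, 0.5) log2 units | clearly detectable at the default replication |
| cross-modality correlation ρ | 0.7 | strong planted concordance |
| counts | NB with variance μ + αμ², α = 0.05, baselines log-normal(5, 1), library factors U(0.7, 1.3), 4 replicates per condition | typical bulk count structure |

Planted effects are correlated across modalities through a shared latent
draw: a gene is "regulated" with the RNA differential fraction; regulated
genes draw one random sign and a trivariate normal deviate with pairwise
correlation ρ, and the gene's three effects are inherited by its
promoter-linked ATAC and G4 peaks.  Background (non-promoter) peaks draw
independent effects at their own modality fractions.  Because
non-regulated features have exactly zero effect in every modality, the
Pearson correlation of planted fold changes across any shared feature set
approaches `(m² + ρ·s²)/(m² + s²)` for effect magnitude N(m, s) — slightly
above ρ, which the truth table records exactly.

Copy-number ratios act multiplicatively on case-sample means for ATAC and
G4 counts only; expression counts are left copy-neutral so that
integration tests isolate the chromatin-side correction.  The
`GroundTruth` table records per-feature fold changes, statuses, strands
and CNRs, plus the realized promoter-enrichment fold.

**Planting a target promoter-enrichment fold.**  The background rate p₀ at
which a random peak overlaps any promoter window is computed exactly by
interval arithmetic over legal start positions (averaged over the sampled
peak-width distribution), not by Monte-Carlo placement; the promoter
fraction needed for a target fold F is then `p₀(F−1)/(1−p₀)`, which
accounts for background peaks that land in promoters by chance.  This
removes the placement noise that otherwise dominates a ±15% recovery
check.

What the generator does **not** emulate: read-level data (no FASTQ,
fragment lengths or Tn5 insertion model), sequence content (no G-runs, so
no motif analysis), peak-calling artifacts, overdispersed library
composition effects, or biological confounding between G4 presence and
expression level.  Passing tests therefore demonstrate that the
*statistical machinery* recovers planted structure under its own noise
model — not that any biological conclusion transfers to real data.

## Copy-number normalization

Segments (CNVkit-style `chromosome/start/end/log2` TSV; extra columns
ignored) are converted to CNR = 2^log2.  Each peak is assigned its
overlapping segment — largest overlap wins when a peak spans a boundary,
ties to the lower segment start — or the closest segment by edge distance
when none overlaps.  CNR ≥ 1 divides case-sample counts by the CNR; CNR < 1
multiplies control-sample counts by it; CNR = 1 is a no-op and sits on the
≥ 1 branch.  Scaled counts are rounded half-up so the count-based test
keeps an integer contract; peaks on chromosomes without segments keep
CNR = 1 with a warning rather than being dropped.

## Differential testing

A deliberately transparent stand-in for DESeq2/edgeR/DiffBind — parity is
claimed with planted truth, not with those tools' numerics:

- **Normalization**: median-of-ratios size factors; optionally a trended
  alternative that regresses each sample's M = log2(count) − log2(reference)
  on A against the geometric-mean pseudo-reference with a lowess fit
  (span 0.5, pseudo-count 0.5) and uses the fitted trend as a
  per-feature-per-sample offset, for data with a skewed MA plot.  In the
  untrended limit the offsets reduce to log2 size factors.
- **Dispersion**: per-feature method of moments, α̂ = max(0, (s²−μ)/μ²)
  pooled across the two conditions with df weights, floored at 1e-8.  Raw
  per-feature estimates on 4–6 replicates are noisy enough to leave the
  Wald test anticonservative (empirical type-I ≈ 0.08–0.10 at nominal
  0.05), so the pipeline default shrinks 75% of the way toward the
  across-feature mean — an edgeR-common-dispersion-flavoured moderation
  that restores type-I error to ≈ 0.05–0.06 while leaving fold-change
  recovery untouched.  `dispersion_shrink=0` disables it.
- **Test**: per-feature NB log-link model with a two-level condition
  factor.  Group rates solve the NB score equation by vectorized Newton
  iteration; an all-zero group receives half a pseudo-count so the fold
  change stays finite; Wald z = β̂/se(β̂) with se from the Fisher
  information Σ μ/(1+αμ), two-sided normal p.  Features all-zero in both
  conditions are flagged NA and excluded from the BH m.
- **Calls**: Benjamini–Hochberg adjustment; status up/down iff
  p_adj < α (default 0.05) with the matching fold-change sign, else nd.

No fold-change shrinkage, Cook's distance filtering or independent
filtering.

## Permutation enrichment

Observed overlap (default: number of subject features hit by ≥ 1 query
interval; pair counting available) is compared to a null built either by
**genome shuffle** — every query interval relocated uniformly among legal
start positions, length preserved, excluded regions rejected (10⁴ attempts
per interval), same-chromosome placement by default with a
length-proportional cross-chromosome mode — or by **universe resampling**
(|query| elements drawn without replacement, e.g. DE-gene TSSs within
active-gene TSSs).  The summary reports the permutation mean/sd, z score,
normal-reference p, fold = observed/expected, and an add-one empirical
p = (1 + #{null ≥ observed})/(1 + n_perm) (mirrored for depletion), which
can never be 0.

## Feature annotation

Each interval gets exactly one category by fixed precedence: promoter/TSS
(TSS ± 3 kb) > 5′UTR > first exon–intron junction > first exon > first
intron > other exon > other intron > 3′UTR > intergenic.  "First" follows
transcription order; the junction category requires the interval to cover
the boundary coordinate (both flanking bases).  The fixed order makes
category tallies reproducible where categories overlap.

## Strandedness

A G4 peak intersecting in-vitro hits on the Watson strand only is called
Watson; Crick symmetric; both strands → ambiguous; none → unassigned
(minimum hit overlap 1 bp, configurable).  "Transcribing strand" is
interpreted as the template strand read by the polymerase: for a "+" gene
the template is Crick, so a Crick-called G4 on a "+" gene is classified
transcribing and a Watson-called one non-transcribing, mirrored for "−"
genes.  Ambiguous/unassigned calls and unlinked peaks are not callable.

## Concordance quadrants

Two differential contrasts are joined over the shared tested universe;
features significant in both fall in one signed quadrant (++/−−/+−/−+).
Each quadrant is tested hypergeometrically with sign-stratified margins
(for ++: K = #A-up, n = #B-up, population N = shared tested features;
`population="double_diff"` restricts N to doubly-differential features).
p_upper = P(X ≥ k) tests enrichment, p_lower = P(X ≤ k) depletion; they
share P(X = k).  Features tested in only one contrast are excluded from N
with a warning.

## Integration

- **Linking**: a peak links to the nearest TSS strictly closer than 3 kb,
  distance measured from the nearest peak edge (0 when covering the TSS);
  midpoint distance available behind a flag; ties go to the smaller gene
  id.
- **Expression**: TPM (sums to 10⁶ exactly) and RPKM with in-feature
  library size; activity via a zFPKM-style half-Gaussian fit — the mode of
  the log2 distribution from a Gaussian KDE on a 2¹²-point grid, σ from
  the mean of the upper half times √(π/2), inactive below z = −3.  The KDE
  bandwidth is Silverman's rule inflated 2×: the argmax of a rule-of-thumb
  density jitters by ~±0.3 log2 units from sample noise near a flat mode,
  and oversmoothing trades that variance for negligible bias in the
  roughly symmetric distributions this is applied to.
- **Proximity decay**: ATAC peaks indexed per G4 site by signed rank
  (0 = overlapping; ±k = k-th non-overlapping peak toward
  increasing/decreasing coordinates — the decay readout is symmetric in
  |rank| so the orientation convention is cosmetic) and by nearest-edge
  distance bins; per-offset Pearson r between the two modalities' fold
  changes, NA below 3 pairs.
- **Interaction**: rna_log2fc ~ atac_status * g4_status with both 3-level
  factors under sum-to-zero contrasts and type-III F tests (each term's
  columns removed against the full fit), so main effects remain testable
  in the presence of the interaction.  Empty factor cells leave the design
  rank-deficient; affected terms are flagged NaN rather than silently
  dropped — on strongly concordant studies the discordant cells are
  genuinely empty and the interaction is not testable, which the analysis
  driver reports as such.

## Validation strategy and numerical checks

- All interval operations are property-tested against O(n²) brute-force
  oracles; hypergeometric tails against exhaustive enumeration for
  N ≤ 25; the type-III F against a full-vs-reduced residual-sum-of-squares
  fit.
- Calibration tests draw query sets from the null itself (shuffle-null
  folds ≈ 1, empirical p uniform; interaction p uniform under a
  no-interaction simulation) and power tests recover planted effects
  (log2fc bias < 0.15, 3× promoter fold within ±15%, planted strands
  recovered exactly for unambiguously covered peaks).
- The null-calibration fixture uses regularly spaced TSS-like subject
  points with long query intervals: the overlap count is then tightly
  concentrated (sub-Poisson), so "fold ≈ 1" is a sharp statement and the
  discreteness makes the add-one empirical p conservative at the 0.05
  boundary.
- The end-to-end correlation recovery compares the estimated cross-modal
  Pearson r to the value the generative model implies *computed from the
  truth table*: the planted correlation attenuated by each modality's
  estimation noise (errors-in-variables, λ = sd_true/√(var_true + mean se²)).
  After copy-number correction the gap is < 0.01 at the default study
  size.
- Problem sizes used by the checks (5000 features × 4–6 replicates for
  differential/CNV calibration, 600–1200 peaks with 200 permutations for
  enrichment, 200 × n = 3000 runs for the interaction model) keep the full
  suite in the low minutes on one CPU while leaving every tolerance
  comfortably resolvable.

## Known limitations

- The Wald test with moderated dispersions is slightly anticonservative
  for genuinely heterogeneous per-feature dispersions; the moderation
  weight is a config knob, not estimated from the data.
- The loess offset normalization assumes a common trend across samples of
  the same condition and falls back to size factors on degenerate A
  ranges.
- `shuffle` is rejection sampling; pathological excluded sets (> 90% of a
  chromosome) can exhaust the attempt budget and raise.
- Strandedness inference treats any single opposite-strand hit as
  disqualifying (ambiguous); no hit-count weighting.
- The hypergeometric quadrant test conditions on the observed margins; it
  does not model selection of the tested universe.
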