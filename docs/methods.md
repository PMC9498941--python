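# Methods

## Processing model

The package targets probe-based RNA counting panels (a few hundred to a few
thousand gene probes plus internal controls) run on tissue-microarray
cores. The raw substrate is an integer probe-by-sample count matrix with
three probe classes: gene probes, negative-control probes (no transcript
target; their signal estimates non-specific background such as undigested,
non-hybridized probes) and a flagged subset of stably expressed
housekeeping genes.

Processing order is fixed:

1. **Sequencing-quality filter.** A sample is excluded when its total read
   count over all probes is below 1.5 million or the relative standard
   deviation (sample SD / mean, computed over all of its probe counts) is
   below 0.1. Both bounds are strict: values equal to the threshold pass.
   A low relative SD indicates a flat, structureless profile — a failed
   assay rather than a shallow one. A sample with zero total has an
   undefined relative SD and fails.
2. **Background subtraction.** Per sample, the arithmetic mean of the
   negative-control probes is subtracted from every gene probe, clamped at
   zero. The mean (rather than a maximum or upper quantile) is the
   minimal-assumption estimator of a probe-independent noise floor;
   clamping preserves count semantics.
3. **adjCPM.** Each sample is scaled to counts-per-million over its
   post-subtraction gene-probe total. A zero total is a hard error: such a
   sample should already have failed the sequencing filter.
4. **Upper-quartile normalization.** Each sample is divided by the 75th
   percentile of its strictly positive values, then multiplied by the
   median of those per-sample quantiles. UQ on positive values reduces
   tissue-specific composition bias; restoring the median keeps the global
   scale stable so log values are comparable across reruns. Quantiles use
   linear interpolation.
5. **Log transform.** `log2(x + 1)` elementwise.
6. **Sample-quality filter.** Each sample's log-expression vector is
   Pearson-correlated (Spearman switchable) against the mean profile of the
   universal-RNA control replicates; samples with R < 0.4 are labelled
   low-quality. Because the correlation labels are only available where
   uRNA controls exist, the operational exclusion rule is an empirically
   calibrated threshold on the mean log expression of the nine housekeeping
   genes: the optimal one-dimensional decision stump against the R < 0.4
   labels (the midpoint threshold minimizing misclassification; ties take
   the smallest threshold, and the degenerate "everything passes" cut is a
   candidate). The final pass flag requires the sequencing filter AND the
   housekeeping threshold; the correlation flag is reported alongside so
   either rule can be audited. Both the correlation labels and the stump
   are recomputed per cohort.

All standard deviations throughout use the n−1 (sample) convention.

## Signature scoring and subtype assignment

Z-scores are computed per gene over a declared sample universe (default:
all tumor plus normal samples passing QC; the amplicon analysis uses tumor
samples only). Samples outside the universe are standardized with the
universe's mean and SD. Genes constant over the universe cannot be
standardized; they score z = 0 and are flagged degenerate rather than
dropped, so signature gene counts stay stable.

A signature is a signed marker set: the score is the mean of +z over
expected-high genes and −z over expected-low genes. Where both directions
exist the signed average is used (the alternative — averaging high genes
only — discards half the information and is not exposed). The assigned
subtype is the argmax over signature scores; exact ties are broken
lexicographically by subtype name and flagged. The margin (best minus
second-best score) quantifies call confidence; reannotation reports flag
calls below a configurable margin (default 0.1) as weak.

Marker selection is a per-gene two-sided Welch t-test (Wilcoxon rank-sum
switchable) of the target group against either the other tumor subtypes or
those plus normals, on log2 expression. Genes pass at a raw p-value
threshold with an optional minimum absolute mean difference; no
multiple-testing correction is applied, because the raw threshold (e.g.
p < 0.005 for closely related subtypes, p < 0.05 for a coarser split) *is*
the selection rule, and its type-I calibration is verified directly in the
acceptance suite.

## Amplicon calling

The neighborhood of an anchor gene is every gene on the same chromosome
whose interval overlaps `[anchor.start − w, anchor.end + w)` with
w = 51 kb by default, half-open overlap on 0-based BED coordinates, strand
ignored (the window is symmetric). The anchor is included by default
(switchable). A sample is amplicon-positive when its mean z over the
neighborhood strictly exceeds 1.5; a mean of exactly 1.5 is not called.

## Concordance

Cross-platform agreement is per-gene Pearson r plus the OLS fit of
platform 2 on platform 1 over shared samples; slopes below 0.75 or above
1.25 (δ = 0.25, configurable) flag systematic under- or over-reading by
platform 2. An optional exclusion list removes probes known to be
incomparable across platforms before fitting; it is a user-supplied file,
never hard-coded.

mRNA-protein agreement uses immunohistochemistry H-scores (0–300). Per
group: medians of log2 expression and H-score, and the within-group Pearson
correlation (undefined under zero variance, reported as missing). When only
H-scores exist, IHC grades can be derived with the bins 0: <1, 1+: 1–100,
2+: >100–200, 3+: >200; positivity is grade 2+/3+. Discordance is
formalized as a percentile-rank gap: each group's median mRNA and median
H-score are ranked across groups on [0, 1]; a gap above 0.3 (configurable)
in favor of mRNA flags `high_mrna_low_protein`, the converse the other
flag. The narrative observation this formalizes — a tumor type expressing
the transcript but almost no protein — becomes a testable, tunable rule.

## Synthetic cohort generator

Counts follow a gamma-Poisson (negative binomial) model with a dispersion
shared across genes: gene g in sample s has expected count
`a_g · e_gs · L_s`, where `a` is a lognormal relative-abundance profile
(log2 SD 2.0 by default, a wide dynamic range typical of expression
panels), `e` collects multiplicative group-marker and amplicon effects
(the per-sample composition is renormalized so the expected library size is
honored), and `L_s` is a gamma-distributed library size (mean 4e6 reads,
CV 0.2 — comfortably above the 1.5M filter for honest samples). An
independent Poisson background (mean 30) is added to every probe and is
all that the negative-control probes carry. Housekeeping genes are pinned
to the 90th percentile of the abundance profile with no group effect; uRNA
replicates are draws around the base profile with no group effects.

Planted QC failures: shallow-sequencing samples are binomially thinned to
~5e5 total reads; low-quality samples have their gene counts permuted
(destroying the correlation with the uRNA reference) and their housekeeping
counts scaled by 0.2 (so the housekeeping filter the correlation labels
calibrate can catch such samples).

Amplification multiplies the 8 neighborhood genes (anchor + 7 neighbors,
placed as a tight cluster within ±51 kb on one chromosome in the emitted
BED) by `2^amplicon_log2fc` in a Bernoulli-selected fraction of tumor
samples (default prevalence 0.1, a typical pan-cancer amplified fraction).

H-scores for tracked genes follow a saturating monotone map of latent
protein: latent = (sample's realized log2 CPM of the gene) × per-group
attenuation in [0, 1]; `H = clip(300·latent/(latent + K) + ε, 0, 300)` with
Gaussian read-out noise ε (SD 15) and K set to the cohort median latent so
the median sample scores H ≈ 150. Coupling latent protein to the realized
(not expected) transcript abundance makes within-group mRNA-protein
correlation respond to the attenuation factor, which is the planted signal
the discordance analysis recovers. Attenuation 0 produces an
mRNA-expressing, protein-null group. IHC grades derive from the noisy
H-score through the default bins.

Everything flows from one integer seed; identical configurations produce
byte-identical cohorts, count files and manifests.

### What the generator does not emulate

FFPE degradation chemistry, probe GC bias, isoform structure, batch/TMA-
block effects, correlated gene-gene expression beyond the planted marker
and amplicon structure, and zero-inflation beyond what background
subtraction induces. Passing recovery tests therefore demonstrates that the
algorithms implement their definitions and detect their planted signals at
the stated effect sizes — not that those effect sizes, or the filters'
published thresholds, are optimal for any particular real cohort.

## Validation design and problem sizes

The validation suite (tests plus `scripts/acceptance.py`) measures, on
freshly generated cohorts: exact recovery of 5+5 planted QC failures in a
200-sample cohort; entry-level agreement of background subtraction, adjCPM
and UQ with independently coded loop oracles on 500×50 random matrices
(tolerance 1e-9); z-score moments to 1e-9; type-I calibration of marker
selection at p < 0.005 over 20 null cohorts of 2000 genes × 60 samples
(pooled selected fraction inside the exact binomial 99% interval); argmax
subtype recovery ≥ 95% at marker log2FC 2 (4 × 50 samples, 30 markers per
group) and chance-level accuracy at log2FC 0; amplicon sensitivity ≥ 0.95
with FPR ≤ 0.01 at 10% prevalence among 500 tumors; OLS slope recovery
within 3 standard errors; unique flagging of a fully attenuated group among
8; and byte-identical pipeline reruns. The null-calibration cohorts use a
narrower abundance spread (log2 SD 1.0) and zero background so every gene
is comfortably expressed: the property under test is the calibration of the
selection rule, which count clamping and near-zero genes would conflate
with expression-level artifacts.

## Known limitations

* The housekeeping stump needs informative correlation labels; on a cohort
  with no low-quality samples it degenerates to "everything passes", which
  is the intended behavior but means the threshold is not transferable
  across cohorts.
* The UQ rescaling constant (median of per-sample upper quartiles) is
  cohort-dependent; expression values are comparable within a run, not
  across differently composed cohorts.
* Welch-t marker selection assumes approximate normality of log2
  expression; for heavily zero-inflated genes the Wilcoxon option is the
  safer choice.
* Amplicon calling is an expression-level proxy: it cannot distinguish
  genomic amplification from coordinated transcriptional upregulation, and
  performs no significance testing.
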