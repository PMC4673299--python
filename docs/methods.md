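# Methods

## Scope and model

The package reimplements the classic paired tumor/normal microarray
workflow for mixed lncRNA/mRNA probes. The analysis unit is the probe
(no probe-to-gene summarization); values are log2 intensities
throughout. The statistical pipeline is deliberately the published
one — raw-p thresholds, a fixed fold-change cutoff, marginal
hypergeometric tests — rather than a modernized variant (no moderated
variances, no GO-DAG propagation); BH q values are computed and
reported alongside so users can apply FDR-based calls if they prefer.

## Preprocessing

**Quantile normalization** maps every sample column onto the reference
distribution formed by averaging the columns' order statistics. Ties
within a column receive the mean of the reference values over the tied
ranks. On tie-free data the transform is exactly idempotent and leaves
within-column rank order unchanged; with ties, tied runs collapse to
their run mean on the first pass (the behavior of the standard
algorithm, checked in tests against `limma::normalizeQuantiles`).

**Flag filtering** keeps a probe when, in at least one condition, the
fraction of samples flagged "P" reaches `flag_min_fraction`
(default 1.0 — all samples of that condition). The phrase "detected in
at least one of the two conditions" is ambiguous about partial
detection, so the fraction is exposed as a parameter. The pipeline
normalizes before filtering by default; a config switch
(`filter_before_normalize`) flips the order, which the source tools do
not document.

## Differential expression

Fold change is `2^|mean_tumor − mean_normal|` with direction reported
separately ("up" = higher in tumor). The default test is the
pooled-variance unpaired t test: recomputing the bundled printed
tables shows the printed two-decimal p values match this flavor for
all 60 rows (maximum discrepancy 0.005, i.e. rounding), while a paired
test does not (0.040 vs the printed 0.03 on the top probe), so the
published analysis evidently ignored the pairing. Welch and paired
modes are selectable. Degenerate inputs: two identical constant groups
give p = 1 by convention; constant groups with different means give
p = 0. DE calls use raw p ≤ 0.05 and FC ≥ 2.

**Clustering.** Items are clustered by average linkage on
d = 1 − Pearson correlation. When samples are the items, each probe
profile is mean-centered across samples first (`center_probes=True`).
This is the heat-map convention — the displayed quantity is the
deviation from the probe's mean — and it is what makes condition
groups separate: on the bundled 30-probe lncRNA table, raw-intensity
correlation leaves one tumor sample closer to the normals (its absolute
intensities are intermediate), while gene-centered correlation cleanly
bipartitions {C1,C2,C3} from {N1,N2,N3}. Zero-variance profiles have
undefined correlation and are assigned dissimilarity 1 to every item,
with a logged warning. Merge ties are resolved by scipy's deterministic
ordering.

## Co-expression network

Edges connect DE lncRNA–mRNA pairs with |r| ≥ 0.99 across all sample
columns (six, in the reference design). The absolute-value rule is the
default because co-expression conventionally includes anti-correlation;
`correlation_signed=True` applies the literal one-sided reading.
Correlation uses all samples rather than within-condition subsets.
Genomic distance is the gap between gene spans (closest ends, 0-based
half-open, 0 when overlapping or abutting); pairs on different
chromosomes carry a sentinel. An edge is *trans* when the chromosomes
differ or the gap exceeds 100 kb, *cis* otherwise — "on the other
allele" in the source description is read as "on a different
chromosome", the only geometric reading that composes with a distance
rule. Both modes are retained in the edge list; the TF analysis
consumes the trans edges.

## Enrichment machinery

The shared statistic is the hypergeometric upper tail
P(X ≥ k | N, K, n), computed via `scipy.stats.hypergeom.sf` (log-space
internally) and validated in tests against exact rational enumeration
for every parameter combination with N ≤ 12. Sets are intersected with
the universe before counting; sets with zero overlap are omitted
(k = 0 would give p = 1 anyway, and omitting them keeps BH families
meaningful). The universe defaults to all mRNA probes surviving the
flag filter — the population the correlations were computed over. For
the TF network, BH runs jointly across the full TF × lncRNA test
matrix and associations must satisfy both p < 0.01 and q < 0.01. TFs
are ranked by distinct associated lncRNAs, ties by median p, then id.

## qPCR quantification

Replicate Ct values are averaged (arithmetic mean, the Livak
convention); ΔCt = Ct_target − Ct_reference per (patient, condition);
ΔΔCt = ΔCt_tumor − ΔCt_normal with the patient-matched normal as
calibrator; relative expression is 2^-ΔΔCt. The summary across
patients is the median log2 fold with standard error sd/√n (0 when
n = 1). Log base 2 is used for consistency with the array fold
changes. No amplification-efficiency correction is applied.

## Synthetic cohort

The generator is the test substrate standing in for undeposited raw
arrays. Defaults mirror the reference design: 1,000 lncRNA + 1,000
mRNA probes, 3 tumor/normal pairs, baseline log2 intensities
N(8, 2²), residual noise sd 0.5, planted effect ±3 log2 units
(≥ 2-fold with margin), three co-expression modules of 20 probes
(half lncRNA, half mRNA), one annotation term and one TF target set of
size 50 linked to each module, and detection flag "A" below intensity
1.0.

Structural choices, and why:

* **Patient effects** (`patient_sd`, 0.5) are per probe-patient and
  patient-block — added to both of a patient's samples — so they
  cancel from the tumor−normal contrast while adding realistic
  within-group variance.
* **Effect heterogeneity** (`de_patient_sd`, 0.2) jitters each
  differential probe's tumor shift per patient. Without any
  per-sample decorrelation, every strongly differential probe would
  correlate near ±1 with every other through the shared tumor/normal
  split, and the r ≥ 0.99 edge rule could not distinguish module
  co-membership from mere co-differential-expression.
* **Module latents** are per-sample trajectories drawn in the
  orthogonal complement of the intercept and the tumor indicator,
  orthogonalized across modules, and scaled to exactly
  `module_amplitude` (0.5) per-sample sd. Orthogonality to the tumor
  contrast keeps the latent out of the group-mean difference;
  orthogonality across modules prevents chance collinearity (with
  three patients, unconstrained latents are frequently near-collinear,
  which would fire hundreds of cross-module edge false positives at
  once); exact scaling makes the latent's contribution to the pooled
  t-test denominator a constant rather than a heavy-tailed draw.
  Members add private noise `module_noise_sd` (0.04), keeping
  within-module |r| ≥ 0.99 across six samples.
* **Mid-range planting.** Baselines of differential probes are drawn
  from a truncated normal within one sd of the mean, so the shifted
  condition stays inside the occupied intensity range. Effects planted
  in the tails are censored by rank-based normalization (exactly as a
  real array saturates outside its linear response range), which would
  silently shrink realized fold changes.
* **Gene sets**: linked sets contain their module's mRNAs plus random
  background genes up to `set_size`; unlinked sets are uniform draws,
  so their overlap with any module follows the hypergeometric null.
* **qPCR tables** are generated for an independent validation cohort
  (12 patients, triplicates) with expected ΔΔCt equal to minus the
  planted log2 effect, Gaussian replicate noise on the Ct scale
  (ΔΔCt algebra is linear in Ct) and per-patient biological jitter of
  the effect.

All draws flow from one `numpy.random.default_rng(seed)`; identical
(params, seed) reproduce every output bit for bit.

What the generator does **not** emulate: dye/probe-affinity bias,
spatial artifacts, background correction, batch structure, intensity-
dependent variance, or correlated null probes beyond the planted
modules. Passing the recovery study therefore shows the pipeline's
statistics behave as designed under their own assumptions — not that
those assumptions hold on any particular real array.

## Recovery study (problem sizes)

The acceptance-level study runs the full pipeline on 20 simulated
cohorts at the default conditions (2,000 probes, 3v3) and pools
results: DE sensitivity on planted probes and false-positive rate on
nulls; precision/recall of edge detection against module co-membership;
recovery of every planted TF–lncRNA link at p < 0.01, q < 0.01; and
the spurious-association rate after permuting TF target labels (two
permutations per cohort). Twenty seeds keep the study under a minute
on one CPU while leaving the pass margins wide (observed: sensitivity
≈ 0.98 vs the 0.9 bound; precision ≈ 0.92 vs 0.8; all links in 20/20
seeds vs 18/20).

## Known limitations

* Genome-wide result counts of the motivating study are not
  reproducible (raw arrays undeposited); the bundled tables cover only
  the printed top-30 rows, and real GO/KEGG/ENCODE content is replaced
  by user-supplied or synthetic GMT files.
* Quantile normalization is not idempotent on tied values (inherent to
  the algorithm).
* With six samples, |r| ≥ 0.99 is an extremely aggressive edge rule;
  on real data it mixes co-regulation with co-differential expression,
  and the network should be read accordingly.
* The pooled unpaired t test ignores the pairing and is conservative
  when patient effects are large; the paired mode is provided but is
  not the published procedure.
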