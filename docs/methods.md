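# Methods

`phosq` implements the quantitative stages of a multi-batch, isobarically
labeled (TMT 10-plex) phosphoproteomics study of paired tumor (T) and
non-tumor adjacent tissue (NAT) biopsies, sampled before and after drug
treatment, with a pooled cell-line mixture serving as the reference channel
in every batch. This note records the models, the defaults and why they are
set where they are, and what the synthetic benchmark does and does not show.

## Input model and identification-level filters

Inputs are search-engine site- and protein-group tables (tab-separated, one
reporter-intensity column per batch/channel; a configurable column map
absorbs dialect differences). A reporter intensity of 0 means "not
quantified" and is treated as missing — downstream processing is on the log2
scale, where 0 is undefined.

Filters applied before quantification:

* **class-1 sites**: localization probability strictly greater than 0.75 —
  the conventional confidence cut for claiming the phosphate sits on the
  stated residue. The comparison is strict (`> 0.75`, not `>=`).
* **artifact removal**: rows flagged as decoy ("reverse") or potential
  contaminant are dropped.
* **protein groups**: at least 2 razor+unique peptides.

Site identity for every cross-table join is `(gene symbol, residue,
position)`, rendered as `GENE_S123`; kinase-substrate databases are keyed
that way, so joining on accession would lose most edges. The protein
accession is the fallback when the gene symbol is absent.

Reported percentages (residue composition, presence categories) are rounded
half-up to one decimal, matching the usual reporting style for these
summaries.

## Two normalization routes

**Group route** (feeds group-level statistics), in this order:

1. log2 transform;
2. subtract, per feature, the mean of the batch's reference channels. The
   reference is a pooled cell-line mixture present in every batch; the
   subtraction is done *within batch*, the only arrangement that cancels
   batch-specific labeling/loading efficiency and puts all batches on the
   common reference scale;
3. median-center each sample channel (observed values only);
4. keep features quantified in at least one sample of *every* batch;
5. impute each feature's remaining missing cells with the feature's minimum
   observed value — the standard left-censoring surrogate for reporter-ion
   data, where missingness concentrates at low abundance. The per-sample
   minimum is available as a config alternative;
6. remove residual batch effects with the parametric empirical-Bayes
   location/scale model (below).

**Individual route** (feeds single-patient fold changes): log2 and
per-channel median centering of the clinical samples only. Individual
comparisons are always within one patient, and the two samples of such a
pair share their batch-level handling, so reference subtraction, imputation
and model-based correction are unnecessary and would only add noise;
co-quantification is required site by site instead.

Whether to impute before or after reference subtraction, and whether group
tests should exclude imputed cells, are genuinely open choices; this package
follows the narrative order above and tests on the imputed matrix.

## Empirical-Bayes batch correction

Per feature *g* and batch *b* the model is
`x = alpha_g + gamma_bg + delta_bg * eps`. The fit standardizes each feature
by the batch-size-weighted grand mean and the pooled residual variance, then
estimates per-batch location (`gamma_hat`, the batch mean of the
standardized data) and scale (`delta2_hat`, the batch variance, ddof 1).
Moment-matched priors — normal across features for gamma, inverse-gamma for
delta² — shrink the per-feature estimates through iterated conditional
posterior means; convergence tolerance is 1e-6 (relative change) with a
200-iteration cap, conventional and cheap at this scale. The adjusted value
is `pooled_sd * (z - gamma*) / delta* + grand_mean`. The covariate design is
intercept-only: no biological covariates are preserved explicitly, which is
conservative when group sizes are balanced across batches (the synthetic
design assigns samples round-robin for exactly that reason). Non-parametric
priors are out of scope.

Numerical notes: a single-batch input is returned bit-identically (nothing
to correct); a batch with fewer than two samples is an error (scale not
estimable); with shrinkage disabled (`shrink=False`, used by the test
oracle) the adjustment reduces to the per-batch standardization closed form,
and a feature with zero within-batch variance is left unscaled there rather
than divided by zero. Exact grand-mean preservation holds for the
unshrunk adjustment; EB shrinkage perturbs it at the 1e-3 level because the
posterior batch locations differ from the raw batch means.

## Differential phosphosites

Group contrasts report `log2FC = mean(A) - mean(B)` and a two-sided test:
Welch's t with Satterthwaite degrees of freedom for independent groups
(HER2-status contrast), or a paired t on per-patient differences for the
treatment contrast. Classes follow the joint rule: significant when
`|log2FC| > 1` (strict) and `p < 0.05`; tendency when `|log2FC| > 1` and
`0.05 <= p < 0.1`; direction from the sign. No multiple-testing correction
is applied on the primary path — raw p-values with a fold-change gate are
the reporting convention this pipeline reproduces — but Benjamini–Hochberg
adjustment is available as an option. Degenerate zero-variance rows yield
`p = 1` when the means agree and are flagged `not_testable` otherwise.

Individual comparisons are fold-change-only (`|log2FC| > 1`) over
co-quantified sites; a site missing in either sample is reported as having
no quantitative value. Pathway overlays summarize per-site classes to gene
nodes with precedence significant > tendency > quantified-only; nodes with
no quantified site are "not quantified".

## Over-representation analysis

The ORA statistic is the exact hypergeometric upper tail
`P(X >= k | N, m, n)` with k the overlap, m the set size within the
universe, n the hit-list size and N the universe size. The universe is every
gene carrying at least one quantified site in the analyzed matrix — the
defensible local choice when the original web service's universe is unknown
— and is configurable. A gene counts once however many differential sites it
carries. Sets with p < 0.05 are reported significant; enrichment only (no
depletion test).

## Kinase-substrate enrichment (KSEA)

For one comparison's per-site log2 fold changes, with `mean_all`/`sd_all`
the background mean and SD over all quantified sites and `mean_sub` the mean
over a kinase's m matched substrate sites:

    z = (mean_sub - mean_all) * sqrt(m) / sd_all,   p two-sided normal.

Substrate matching is exact on (gene, residue, position); kinases need at
least two quantified substrate sites per comparison (m is counted per
comparison, not in the database), substrates shared by several kinases count
for each, and autophosphorylation edges are retained. Kinases below the
substrate floor in a given comparison are "no information" (grey) there but
may be scored elsewhere. The normal-tail p is validated against a
permutation oracle in the tests rather than against any published heatmap.

Power note: at effect size Δ on m substrates over a unit-SD background the
z-test's two-sided power at α = 0.05 is `Phi(Δ·sqrt(m) − 1.96)`; for Δ = 1,
m = 10 that is ≈ 0.885, so single-kinase recovery rates near 88% are the
expected ceiling for that configuration, not a pipeline defect.

## PCA

Samples are observations, features are centered but not scaled (the default
of the statistical environment this analysis style comes from); components
come from a full SVD and each loading vector's largest-magnitude entry is
made positive so signs are reproducible. Features with missing values over
the selected samples are dropped (relevant only for matrices before
imputation).

## Synthetic benchmark

The generator emulates the study design: 4 TMT 10-plex batches, each with 6
clinical and 2 reference channels (2 unused); 24 clinical samples — 4 HER2+
patients × {pre, post} × {T, NAT} and 4 HER2− patients × {T, NAT} — assigned
round-robin to batches so biology is not confounded with batch. Per log2
value:

    base_f + effects + gamma_bf + delta_bf * N(0, noise_sd)

with defaults: 3,000 sites on ~1,000 genes (residues at 82.5/15.8/1.7%
S/T/Y), base ~ N(23, 2) on the log2 scale, additive batch effects
gamma ~ N(0, tau=1), multiplicative effects delta ~ U(0.7, 1.4), reporter
noise SD 0.5 — a typical reporter-ion CV once channel loading is bridged.
Biological effects are concentrated on the substrate sites of 6 active
kinases per contrast (tumor-vs-NAT, HER2 status, treatment), shifted by ±1
log2 unit, plus 150 extra differential sites per group contrast at ±2 (so
the |log2FC| > 1 gate is meaningfully exercised). Missingness is
missing-not-at-random: logistic left-censoring on the log2 value (midpoint
21, slope 0.8, ≈ 15–25% missing overall, concentrated at low abundance).
About 90% of sites draw localization probability above 0.75 and ~1% each are
flagged decoy/contaminant. The kinase-substrate network has shifted-geometric
substrate counts (min 1, so the two-substrate floor is exercised) and ~20%
of edges point at unmeasured sites, as a curated database would. All draws
come from one seeded generator; outputs are byte-reproducible per seed.

What the benchmark does **not** emulate: peptide-level aggregation, isotope
impurity between TMT channels, ratio compression from co-isolation,
correlated biological covariance between sites on one protein, and real
kinase-substrate annotation bias. Passing tests therefore demonstrate that
the pipeline's statistics behave as designed under the stated generative
model, not that the biological conclusions of any particular dataset are
correct.

## Problem sizes

The test suite and the reproduction script run at the generator defaults
(3,000 sites, 4 batches, 24 clinical samples), with calibration checks at
5,000 null kinases, 200 recovery replicates, 1,000-feature null contrasts,
and permutation oracles of 100,000 draws on 20 small instances — sizes at
which every calibration quantity has a Monte-Carlo error comfortably inside
its test tolerance.

## Known limitations

* Phosphosite abundance is not normalized to protein abundance; observed
  site changes conflate phosphorylation stoichiometry with protein-level
  change, exactly as in the upstream analysis style this package mirrors.
* The EB batch model assumes batch effects are location/scale per feature;
  interaction-type artifacts (batch × group) are out of model.
* With 6 clinical samples per batch, per-batch location estimates are noisy;
  under a true null the correction perturbs values at ~0.25 RMS of the
  residual scale (EB shrinkage halves the raw estimate noise but cannot
  remove it).
* Minimum-value imputation biases low-abundance fold changes toward zero and
  deflates within-group variance for heavily censored sites; tendency-class
  calls on such sites should be read cautiously.
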