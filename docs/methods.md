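# Methods

This note documents the models implemented in `peroclock`, the defaults
they ship with, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer from the code.

## Data model

The unit of analysis is the CpG: a beta value in [0, 1] is the methylated
fraction measured at that site in one sample.  A `MethylationDataset`
bundles the CpG × sample beta matrix, per-sample annotations (species,
stock, tissue, sex, age in years, mating-system and altitude labels,
maximum lifespan) and a probe manifest (chromosome, 1-based position,
adjacent gene, region class).  Missing betas are explicit NaN and are
handled pairwise-complete by every per-CpG statistic, which reports the
per-CpG sample count actually used (`n_used`); nothing is imputed.
Alignment of a beta matrix with a sample sheet sorts both axes by id, which
makes it idempotent and invariant to input order.

A bundled table supplies maximum lifespans for the five *Peromyscus*
species (californicus 5.5 y, eremicus 7.4 y, leucopus 7.9 y,
maniculatus 8.3 y, polionotus 5.5 y) and human (122.5 y); user-supplied
values override it.  The interspecific hybrid
(*P. polionotus* × *P. maniculatus*) has no published maximum lifespan and
is assigned its polionotus parent's 5.5 y — it only matters for
relative-age analyses, which the hybrid's 0.083–0.25 y samples barely
constrain.  Manifest coordinates are 1-based inclusive (array-manifest
convention); any BED-style export would convert to 0-based half-open.

## Age transforms

Clocks regress a transform F(age) rather than raw age:

* `log_linear` (default): F(x) = log(x + c) − log(m + c) for x < m and
  (x − m)/(m + c) for x ≥ m.  Logarithmic during development, linear in
  adulthood, continuous and strictly increasing at the maturity age m.
  Defaults: m = 0.5 y for *Peromyscus*, 15 y for human, offset
  c = 0.1 y — all configurable.  The exact functional form used for the
  published clocks is not fully specified in the public text, so this
  standard log-linear form is adopted as the package's own choice.
* `relative`: F(x) = x / max lifespan, a value in [0, 1].  The dual-species
  relative-age clock trains on untransformed relative age and clamps
  predictions to [0, 1] before reporting; no further transform of relative
  age is applied (kept as a config knob).
* `identity`: raw years, for completeness.

Forward and inverse transforms round-trip to better than 1e-9 over
0–93 years (tested).

## Clock fitting

Elastic-net linear regression of F(age) on beta values with mixing
parameter α = 0.5 (fixed midway between ridge and lasso, not optimized).
Predictors are standardized inside the fit and coefficients are
back-transformed to the beta scale, so stored clocks apply directly to beta
matrices.  The penalty strength is selected by internal k-fold
cross-validation (k = 10) minimizing mean squared error over a 16-point
log-spaced path down to 1% of the maximal penalty; coordinate descent uses
seeded random feature selection (tolerance 2e-3, max 1500 iterations), so
the same seed reproduces the same path, penalty and coefficients exactly.
The path length and stopping tolerance were chosen to keep a full
leave-one-out evaluation of a 150 × 2000 dataset in the tens of seconds at
a cross-validated R² indistinguishable (< 0.002) from a 10× slower dense
path.  Internal CV folds are stratified by (species, tissue) so no fold
loses an entire stratum.  With fewer than four training samples internal CV
is impossible; the fit then falls back to a fixed penalty of 5% of the
maximal penalty (this only arises in degenerate toy settings).

Accuracy is reported by leave-one-sample-out cross-validation: each sample
is predicted by a clock refit (penalty re-selected) on the other n − 1,
giving one unbiased DNAm-age per sample; we report the Pearson correlation
R between DNAm age and chronological age and the median absolute error in
years, both computed after inverting the age transform.

Dual-species clocks pool deer-mouse and human samples into a single
regression.  For the chronological target the log-linear transform uses a
species-specific maturity; for the relative target no per-species parameter
is needed beyond the lifespan.  Accuracy is reported pooled and restricted
to each species: the pooled correlation is inflated by the 25-fold age-range
gap between the species, so the restricted value is the honest per-species
accuracy.  Samples are unweighted by default (an optional per-species
weight exists); the study-scale imbalance (1205 humans vs ~138 deer mice)
is emulated at reduced, balanced size in the bundled benchmarks.

## QC clustering

Dissimilarity is 1 − interarray Pearson correlation over pairwise-complete
CpGs; zero-variance samples (undefined correlation) are excluded with a
warning.  Average-linkage (UPGMA) trees are built with scipy and verified
against an independent naive implementation to 1e-12.  `cut_tree` assigns
clusters from merges strictly below the cut height, so height 0 yields
singletons.  Outlier flagging combines two signals: membership in a cluster
smaller than `min_cluster_size` (default 2) at the cut (default height
0.03), and mean correlation with the sample's own (tissue, species) group
below a floor (default 0.5 — no published value exists for this floor; it
is exposed in config and recorded in the QC report).  Flagging never
removes samples; removal is a separate explicit step logged by the
pipeline.

The default 0.03 cut presumes array-level interarray correlations
(≥ 0.97 within replicate groups).  Synthetic datasets with strong planted
effects or high noise sit below that correlation and fragment at 0.03; the
pipeline demo therefore cuts at 0.1.  Uniform-noise technical outliers sit
near dissimilarity 1 and are insensitive to this choice.

## EWAS

Within a stratum (typically one tissue, optionally restricted to one
species or stock) the age screen is a per-CpG Pearson correlation with
chronological age; two-sided p-values come from t = r√(n−2)/√(1−r²) on
n − 2 degrees of freedom.  Constant CpGs are reported with r = 0, p = 1 and
a flag.  Correlations are variance-stabilized as Fisher
Z = atanh(r)·√(n−3); |r| = 1 yields a signed-infinity sentinel.  Strata are
combined by Stouffer's method with equal weights across tissues; species
are never pooled this way — cross-species comparison uses the sector
classification and the correlation of Z vectors.

Group contrasts (altitude stock, mating system, species pair) are per-CpG
ordinary least squares of beta on a group indicator plus age; the reported
effect is the group coefficient — the mean methylation difference adjusted
for chronological age — with a two-sided t test.  A covariate-adjusted
linear model was chosen over a correlation screen on the binary label
because the analyses it reproduces are explicitly age-adjusted.  The design
is checked for rank deficiency (group perfectly confounded with age raises
an error); p-values are two-sided throughout with direction carried as the
sign of the effect.

Sector classification of two strata's Z vectors uses two thresholds:
a significance cutoff (default p < 1e-4, two-sided normal quantile
|Z| ≥ 3.89) and a lenient null cutoff (default p > 0.05, |Z| < 1.96).
Shared up/down: both significant, same sign; divergent: both significant,
opposite signs; unique to one stratum: significant there and below even the
lenient threshold in the other; everything else null.  The categories are
mutually exclusive and exhaustive.  Different analyses legitimately use
different significance presets (1e-4, 1e-3, 1e-2); the threshold is always
a parameter.

No genomic-control/inflation correction is applied (an extension point,
deliberately out of scope).

## Enrichment

Regulatory domains follow the GREAT "basal plus extension" rule: basal =
50 kb upstream to 1 kb downstream of the TSS (strand-aware; missing strand
treated as '+' with a warning), extended each way to the nearer of the
neighboring gene's basal domain or 1 Mb, never shrinking below the basal
domain (overlapping basal domains therefore leave no extension, while
extensions of different genes may overlap each other).  A CpG associates
with every gene whose extended domain contains it.

The hypergeometric test is gene-level: the universe is the set of genes hit
by at least one *background* (array) CpG — this conditions out array-design
bias — and a CpG mapping to k genes contributes each gene once.  The
binomial test is region-level: p0 is the fraction of background CpGs inside
the set's domains and the foreground hit count is tested against
Binomial(n_fg, p0).  Gene sets are filtered to 10–3000 genes (counted after
restriction to the universe) before testing; nominal p-values are reported
with Bonferroni and Benjamini–Hochberg columns, adjusted within each
(direction × test) family.  Foreground selection takes the top n CpGs per
direction (default 500) ranked by p, then |effect|, then CpG id (the last
key makes ties deterministic).  Note that with foreground ⊆ background and
a shared CpG-to-gene mapping, a foreground hit implies p0 > 0; the
degenerate p0 = 0 branch is defensive only.

## Synthetic-data generator

Betas are drawn on the logit scale as a sum of a per-CpG baseline
(SD 1.5), shared offsets per tissue / species / stock / sex
(SDs 0.8 / 0.4 / 0.2 / 0.1), planted age and group effects, and i.i.d.
Gaussian noise (SD 0.2), then inverse-logit mapped — so values are strictly
inside (0, 1) and planted effects compose additively.  A logit-normal model
(rather than Beta-distributed draws) was chosen exactly for this additive
closure.  The hierarchy SDs reproduce the qualitative structure of real
multi-species array data: tissue is the dominant clustering split, then
species, then stock, then sex.

Age effects enter as slope × F(age) on a registered subset of CpGs, where F
is the same log-linear transform the clocks regress on (or relative age for
dual-species designs, so the two species share per-relative-age slopes).
Planted effect magnitudes are bounded away from zero —
sign × (0.5 SD + |N(0, SD)|) — because a "planted" effect of essentially
zero would make recovery metrics (sign agreement, relative bias)
meaningless.  Group effects are added to the positive level of a contrast
(monogamous, high-altitude).  Technical outliers are planted by replacing
whole sample columns with uniform(0, 1) draws, destroying interarray
correlation.  Every draw comes from a named substream of the single config
seed, so adding a contrast does not shift unrelated draws and equal configs
are bit-identical.

The default sampling plan mirrors the emulated study: 136 samples across
five species plus one hybrid, tail for all, brain and liver additionally
for *P. leucopus* and *P. maniculatus*, two *P. maniculatus* stocks
(BW low-altitude, SM2 high-altitude), alternating sexes, ages uniform on
0.083–3.6 y.  Stocks are assigned in contiguous blocks so the within-block
sex alternation leaves sex balanced across stocks (an earlier alternating
assignment silently confounded stock with sex).  A 150-sample variant
without the six-sample hybrid (`balanced_species_specs`) is used for clock
benchmarks where every stratum must survive ten-fold internal CV.  The
human stratum (default 120 samples, ages uniform 0–93 y, lifespan 122.5 y)
re-derives the shared per-CpG draws from the same substreams, so it shares
planted age CpGs with the deer stratum of the same config.

What the generator does **not** emulate: probe-level chemistry (type I/II
bias), batch and chip effects, realistic beta bimodality, imprinting /
parent-of-origin effects, age-distribution imbalance between species, and
linkage between neighboring CpGs.  Passing recovery tests therefore shows
the estimators are correct and calibrated under the generative model, not
that real-data accuracies will match; effect sizes were chosen for
testability, not biological calibration, because the emulated study reports
no effect-size scale for its contrasts.

## Benchmark problem sizes

The bundled benchmarks run at desk scale: 1000–2000 CpGs, 40–150 samples,
5–20 seed replicates per property (clock recovery: 150 samples × 2000 CpGs
× 5 seeds; EWAS null: 50 samples × 2000 CpGs × 20 seeds; QC: 40 samples
× 10 seeds).  These sizes make the full suite run in a few minutes on one
CPU while leaving every recovery margin wide (e.g. clock LOOCV R ≈ 0.99
against a 0.85 requirement).

## Known limitations

* The elastic-net path is short (16 penalties, floor at 1% of the maximum);
  severely underdetermined problems that want near-zero penalties would
  need the knobs (`n_lambdas`, `lambda_min_ratio`) opened up.
* LOOCV refits the entire path selection per left-out sample; at thousands
  of samples this is the dominant cost and a k-fold evaluation would be the
  pragmatic substitute.
* `group_ewas` supports one binary contrast with one numeric covariate;
  multi-level contrasts or additional covariates need the design matrix
  generalized.
* Enrichment expects gene annotations with a single TSS per gene; genes
  with multiple transcripts should be reduced to a canonical TSS upstream.
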