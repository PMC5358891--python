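# Methods

`lpscourse` re-implements, as a tested and reusable pipeline, the analysis
pattern used on dense CAGE time courses of stimulated primary cells: a
3-donor, 26-timepoint course of promoter-level expression (tags per
million, TPM) is denoised, averaged and filtered; co-expressed promoters
are clustered on a thresholded Pearson graph with Markov clustering (MCL);
condition-group profiles define an a-priori candidate promoter set; motif
activity response analysis (MARA) decomposes expression into motif
activities; enhancer-promoter timing quantifies whether eRNA transcription
precedes promoter activation; and GWAS summary statistics are tested for
enrichment near a promoter set's TSS. Every stage runs against synthetic
data with planted ground truth, which is what the test suite and the
acceptance script measure.

## Synthetic study design

The generator (`lpscourse.simulate`) emulates the statistical structure of
the real experiment, not its biology. Its defaults are the study
conditions; they were fixed once, from the considerations below, and the
tests measure the pipeline under exactly these conditions.

**Time grid.** 26 timepoints in minutes: every 15 min to 1 h, every
20-30 min to 4 h, hourly to 8 h, two-hourly to 24 h, then 36 h and 48 h —
dense early sampling where immediate-early transcription happens, sparse
late sampling.

**Archetypes.** Each feature draws one of six response archetypes:
immediate-early (gamma-shaped transient peaking at 45 min), early transient
(150 min), intermediate wave (420 min), late sustained (logistic rise
centred at 10 h), repressed (exponential decay, time constant ~6.7 h) and
flat. Default mixture: 0.15 / 0.20 / 0.20 / 0.15 / 0.15 / 0.15. Feature
scales are lognormal (median 30 TPM, log-sd 0.8) over a basal floor
(15% of scale + 2 TPM): promoters have basal activity, so a technical
spike on any cell is detectable.

**Noise model.** Observed TPM factorizes as

    TPM[f,t,d] ~ NB( mu_f(t) * D[f,d] * eps[f,t,d] * L/1e6, alpha ) * 1e6/L

with three deliberately separated variance components:

* `donor_effect_cv = 0.4`: a lognormal multiplier constant across the
  series of one (feature, donor) pair — the large, *shared* inter-donor
  biological variability seen between primary-cell volunteers;
* `donor_noise_cv = 0.05`: independent per-cell lognormal technical noise —
  CAGE replicates are technically highly reproducible;
* `count_dispersion = 0.005` at `library_size = 2e7` tags: near-Poisson tag
  counting with mild overdispersion.

The decomposition matters: a 3-SD rule with an SD *estimated* from an
8-value pool has a Student-t(7) tail, and if all replicate variance were
independent per-cell noise it would falsely replace ~2.5% of cells in any
flat stretch of profile. On real replicate data most of the variance is the
shared donor offset, which appears in both the candidate cell and its pool
and therefore cancels from the decision statistic. Under this model the
smoother's false-replacement rate is ~0.6%, within the 3x-nominal-tail
margin the tests assert. Treating overdispersion as iid per-cell noise is
the unrealistic choice, and it is also the one that breaks the published
rule.

**Spikes.** A fraction `spike_rate` of features receives exactly one
corrupted cell (one timepoint of one donor multiplied by
`spike_magnitude`, default 10), mimicking single-replicate technical
artifacts; the truth mask records every spiked cell, so the number of
flagged truth outliers always equals the number of injected spikes.

**Condition groups.** Four groups (unstimulated monocyte, unstimulated
MDM, IFN-stimulated monocyte, inflammatory-stimulated monocyte) with three
replicate samples each. Features belong to five mean-profile classes; the
"candidate" class (default 10% of features) satisfies both selection
criteria with at least a 1.6-fold margin on every threshold, and each of
the other classes violates at least one criterion with at least a 2-fold
margin, so the planted set is recovered exactly without noise and with
sensitivity/specificity >= 0.95 at the default replicate noise (cv 0.2).

**Motif block.** Motif counts are sparse Poisson(1.2) draws (no all-zero
column); planted activities are smooth two-bump temporal curves, centred to
sum to zero across samples and scaled to unit RMS; log2 expression is a
per-feature baseline plus standardized-counts x activities plus Gaussian
noise (`mara_noise_sd`, default 0.1), exponentiated back to TPM.

**Enhancer-promoter pairs.** Each pair is a sharp transient burst (gamma,
shape 8 — much steeper around the peak than the broad archetype waves,
matching the fast rise-and-fall of induced bursts) with the enhancer kernel
peaking `enhancer_lead_minutes` (default 120) before the promoter's, both
peaks on the sampling grid; eRNA scale is ~5x lower than promoter scale.
Enhancers are placed uniformly within ±500 kb of their promoter's TSS. The
kernel sharpness is what makes grid-argmax peak calling meaningful: with
broad kernels the two grid points around the peak differ by less than the
replicate noise and peak times random-walk.

**GWAS panel.** The panel is a scaled-down model of a genome-wide array:
10,000 variants uniform on a 50 Mb genome (one per 5 kb), null p-values
uniform(0, 1), and a permissive significance threshold `sig_p_threshold =
0.02` chosen so that the expected number of "significant" variants (~200)
and the number of variants per placement window are proportional to the
real regime, where millions of variants are screened at p < 1e-6. Near an
enriched TSS (within `placement_window` = ±30 kb — GWAS signal around
regulated promoters spreads over tens of kb through LD and regional
co-regulation) the probability of significance is multiplied by
`enrichment_fold` (default 10). At the genome-wide threshold itself no
desk-scale panel could plant anything: the fold multiplies a probability of
1e-6. Scaling the threshold with panel size is therefore part of the
scaled-down design, not a free parameter.

What the generator does **not** emulate: CAGE peak calling, sequencing
error, mappability, strand-resolved tag counts, linkage disequilibrium
between variants (variants are independent), or real co-regulation
structure between genomic neighbours. Passing tests therefore demonstrate
correctness of the algorithms under the stated noise model, not performance
on real atlases.

## Preprocessing

**Outlier smoothing.** For each cell (feature f, timepoint t, donor d) the
pool is: the same donor at t-1 and t+1, plus every other donor at t-1, t
and t+1 — 8 values at interior timepoints of a 3-donor design, 5 at the
ends (missing neighbours are dropped, never imputed). A cell deviating more
than `k = 3` sample standard deviations (ddof = 1) from the pool mean is
replaced by that mean. All decisions use the original tensor and are
applied simultaneously: replacement never cascades, and two spikes sitting
in each other's pools can mask one another — the deterministic,
order-independent reading of the rule. When the pool SD is exactly zero,
any deviating value is replaced (the limit of the rule as SD -> 0). Pools
with fewer than 3 members (degenerate designs) are skipped and logged.

**Averaging and filtering.** Donor profiles are averaged arithmetically per
(feature, timepoint). Features are kept when the donor-averaged profile
reaches >= 10 TPM in at least one timepoint **and** has coefficient of
variation > 0.5, where CV = sample SD (ddof = 1) over timepoints divided by
the mean. The thresholds keep the inequality senses asymmetric (>= for the
expression floor, strictly > for CV) deliberately; all-zero profiles have
undefined CV and are removed with a log message. The filter is idempotent.

**Gene aggregation.** Promoter TPM is summed per gene (a promoter mapped to
two genes is a schema error; unmapped promoters are ignored and counted),
and genes whose profile never reaches 20 TPM are dropped — the entry
condition for the transcription-factor sample-network analysis.

## Coexpression clustering

Pearson correlation is computed on donor-averaged TPM profiles (no log
transform by default, since the emulated workflow used none; a log2(x+1)
switch exists). Edges with r >= 0.9 (features) or r >= 0.95 (samples) form
the graph. MCL is implemented in-repo: self-loop weight equals each node's
maximum incident edge weight; the column-stochastic matrix is alternately
squared (expansion) and raised entrywise to the inflation power with column
renormalization; entries below 1e-5 are pruned and columns renormalized;
iteration stops when the iterate changes by less than 1e-8 (cap 200 rounds,
with a warning and best-effort clusters on non-convergence). Clusters are
read off the converged matrix as the spans of attractor rows (non-zero
diagonal), merging attractors with overlapping spans; components smaller
than `min_cluster_size` (default 3) are reported as unclustered. Clusters
are ordered by size, ties by smallest member id. Default inflation is 1.6
for promoter networks and 2.2 for the sample-to-sample network, both
exposed in configuration, as is the edge-weight mode (weights = r by
default, binary optional). The implementation is validated by exact
support agreement with an independently coded naive MCL on every binary
graph of up to 6 nodes, and by ARI >= 0.9 against planted archetypes.

## Candidate selection

Group means are arithmetic means of TPM per condition group, with a
pseudocount (default 1 TPM) stabilizing every ratio at zero expression. The
criteria: monocyte-vs-MDM downregulation is a pseudocounted ratio >= fold
(the explicit fold-change criterion uses 5; the qualitative "A > B"
criteria default to 2, surfaced as a parameter because the emulated
workflow prints no number for them); specific induction requires the
stimulus group's pseudocounted mean to exceed `specificity_fold` times the
largest other group's. All criteria are monotone in the stimulus-group
mean. The SNP-proximal subset takes features whose TSS lies within 2,000
bases (strand-agnostic, boundary-inclusive, single 0-based frame) of a
variant with p < 1e-6.

## Motif activity response analysis

Expression enters as log2(TPM + 1), double-centred (row and column means
removed) so that a feature's mean level and a sample's global shift cannot
masquerade as motif activity. Motif-count columns are standardized
(centred, unit variance) for comparability across motifs of different site
frequency; a `standardize=False` escape hatch exists for algebraic tests.
Activities solve the ridge system A = (N'N + lambda I)^-1 N'E; per-motif
standard errors come from the sandwich sigma^2 * diag((N'N+lambda I)^-1
N'N (N'N+lambda I)^-1) with sigma^2 the residual sum of squares over
(features - motifs) x samples degrees of freedom; activities are re-centred
to sum to zero across samples per motif, and Z = A / dA. lambda defaults to
5-fold cross-validation over {1e-3 ... 1e3} x mean(diag N'N); a singular
system at lambda = 0 raises an error instructing a positive penalty. The
per-motif summary score is sqrt(mean over samples of Z^2), with the SD of Z
across samples carried along for plotting.

## Enhancer-promoter timing

Peak time is the earliest grid point attaining the profile maximum
(earliest-tie-break: deterministic and unbiased under monotone onset);
onset is the earliest grid point with TPM >= max(1 TPM, 10% of the
feature's own peak), absent if never reached — both knobs configurable,
since "detectable activity" needs a numeric rule. Enhancers are paired with
every promoter within ±500 kb on the same chromosome (distance pairing
only; correlation-based enhancer-target linking is out of scope, so in
dense regions spurious pairs dilute the lead statistics — the planted-pair
tables in the truth objects are the clean benchmark). Lead = promoter peak
minus enhancer peak, positive when the enhancer fires first; the summary
reports the fraction of positive leads and, per promoter, the number of
enhancers with onset before the promoter's peak.

## GWAS enrichment

Each variant is assigned once, to its nearest in-set TSS (ties to the lower
coordinate — counting a variant against every TSS whose window covers it
would inflate the observed totals; a count-all-windows mode implements the
alternative reading). Offsets are strand-oriented for stranded TSS
(upstream negative) after converting 1-based variant positions into the
0-based frame. The window of ±1 Mb is divided into 1,000 equal bins of
2 kb ("1000 bins above and below" is read as 1,000 bins total spanning the
2 Mb window, per the figure-caption arithmetic; a bins-per-side mode covers
the other reading via the `n_bins` parameter). Expected counts scale each
bin's total variant count by the panel-wide significant fraction; the
per-bin ratio is observed/expected, undefined (reported missing) in bins
with no variants.

The burden test replaces LD-aware gene-set aggregation (which needs an LD
reference panel) with a resampling scheme: per TSS, variants within
±100 kb are thinned to the best variant per 50 kb sub-block (an LD proxy)
and the score is the maximum -log10 p (note the max over block-maxima
equals the plain window max — the thinning matters only for the optional
sum aggregation, which is exposed via `aggregate="sum"`); the set statistic
is the sum of per-TSS scores; the null re-draws same-size TSS sets without
replacement from a supplied universe, and the empirical p-value is
(1 + #null >= observed) / (1 + M). Index-sorted summation makes identical
sets produce bitwise-identical statistics. Under the null the p-value is
uniform by exchangeability; measured size at nominal 0.05 is ~0.04-0.07
(200 datasets, M = 199), and power against the 10-fold planted enrichment
is ~0.99-1.0 under the default panel.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng` seeded from the
configuration; the CLI writes tables with a fixed `%.17g` float format, so
a fixed config + seed reproduces byte-identical outputs (checked by the
test suite). Reader/writer round trips preserve values to better than
1e-9. Problem sizes in the test and acceptance runs (2,000-feature
smoothing course, 500-feature clustering and MARA runs over 10 seeds,
200-dataset burden calibrations at M = 199 on the 10k-variant panel) are
the package's chosen benchmark sizes; they keep the full suite under a few
minutes on one CPU.

## Known limitations

* Variants are independent; real LD structure, and hence PASCAL-style
  LD-aware aggregation, is not modelled. The burden test's resampling null
  accounts for TSS-set size and the panel's distance structure, not for LD.
* The enhancer-promoter association is purely positional; expression-based
  target linking and bidirectionality scoring of eRNA loci are out of
  scope (the expression tables carry no strand-resolved counts).
* TPM is the only normalization; no batch correction or between-library
  normalization is attempted.
* MCL numerics (self-loop weighting, pruning threshold) follow standard
  practice but are not guaranteed to match any particular external MCL
  binary's defaults on weighted graphs; the in-repo implementation is the
  specification, validated against a naive reference iteration.
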