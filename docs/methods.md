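# Methods notes

This note records the models, defaults, and numerical choices behind
`copath`, and what the synthetic-data generators do and do not emulate.

## The genotype design

All genotype comparisons assume a 2x2 factorial: factor E4 (present in
E4 and E4NLF), factor NLF (humanized-Aβ APP knock-in; present in NLF and
E4NLF), WT carrying neither. `copath.design` enforces the bijection
between factor pairs and the labels WT/E4/NLF/E4NLF.

## Behavior

**Movement states.** Tracking displacement per 0.5 s bin is binarized
with a strict inequality (moving iff displacement > threshold); a
displacement exactly at the threshold scores not-moving. Bout metrics
follow directly: mean bout duration = total time in state / number of
bouts (NaN, never zero, for a state that does not occur), and moving
speed = total distance / total moving time over moving bins only.

**Transition matrices.** Self-transitions are removed at the count
stage, before row normalization, so each non-degenerate row is a
probability distribution over the *other* motifs. A motif that never
transitions away yields an all-NaN row that propagates as missing
through community averaging, animal averaging and group deltas —
degenerate rows never contribute zero probability mass, which would bias
Δ toward negative values. Community-level entries are the unweighted
mean over all motif pairs of the two communities (pairs with zero
observed transitions count as true zeros; fully-missing rows are
excluded via NaN-aware means). Weighting by motif prevalence was
considered and rejected: the source procedure reads as an unconditional
average, and unweighted means keep the estimator independent of motif
usage differences between genotypes.

**Permutation test.** The animal is the exchangeable unit. Group labels
are reshuffled across animals with group sizes preserved; the two-sided
p-value uses add-one smoothing, p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) /
(n_perm + 1), which is valid (super-uniform under the null) for any
number of random permutations and bounds p below by 1/(n_perm + 1). The
default n_perm is 10,000; the calibration experiments use n_perm = 1999
so that α(n_perm + 1) is an integer and the discrete null is exactly
calibrated at α = 0.05.

**Usage clustering.** Dissimilarity is 1 − Pearson r between motif-usage
profiles (range [0, 2]); linkage is average (UPGMA) by default and
configurable — the original analysis used an unstated MATLAB default.
Zero-variance profiles are flagged and excluded from clustering rather
than imputed. The per-genotype "delta usage index" is implemented as
(genotype mean usage − WT mean usage) per motif; this is an
interpretation, as no formula is published for it.

## Sleep EEG

**Staging.** Epochs default to 10 s. Band definitions are delta 1–4 Hz
and theta 6–9 Hz (the bands are named in the literature without limits);
powers come from Welch periodograms, EMG enters as per-epoch RMS.
Decision rules, in order: Wake iff EMG or movement above threshold;
among remaining epochs REM iff theta/delta ratio above threshold *and*
the previous epoch is not Wake (a REM signature straight after Wake is
scored QW); NREM iff delta above threshold; else QW. Thresholds may be
supplied; when auto-derived they are percentiles — EMG and movement at
the 60th over all epochs, the theta/delta ratio at the 85th over
non-Wake epochs, delta at the median over non-Wake non-REM epochs
(sequential conditioning). Percentile auto-calibration makes staging
self-contained per recording but presumes a roughly typical state
composition; with pathological compositions (e.g. continuous wake)
explicit thresholds should be passed.

**Spindles.** Detection band-passes the EEG (10–14 Hz), takes the
analytic (Hilbert) amplitude smoothed over 0.15 s, and converts it to
robust z-scores against the NREM envelope (median and MAD-scaled SD, so
the events themselves do not inflate the baseline). Event cores exceed
z = 2.5; each core is extended to its surrounding z > 1 region
(dual-threshold hysteresis, so measured durations track the true event
extent rather than only its peak); events closer than 0.3 s merge;
events are clipped to their NREM run and kept if their duration is
0.5–3 s with at least 0.3 s of core. Per-event frequency is the median
instantaneous frequency (phase derivative of the analytic signal) over
core samples — markedly more robust at moderate SNR than a raw
zero-crossing count, which remains as the fallback for tiny cores.
Amplitude is the envelope peak. All thresholds are configurable; the
defaults are this package's own operating point, chosen at the knee of
the detector's ROC on synthetic recordings. At an in-band amplitude SNR
of 3 the detector achieves roughly 0.91 recall and 0.91 precision on
average, with seed-to-seed spread of a few points in either direction —
an intrinsic ceiling for envelope detectors when the background carries
Gaussian power in the detection band itself.

**Spikes.** Epileptiform transients are detected on a 15–70 Hz filtered
trace: ongoing delta/theta activity dominates the raw EEG and varies
strongly between states, whereas ~30 ms transients keep most of their
energy above 15 Hz where the background is small and stationary.
Threshold: 6 robust SD (MAD-scaled) of the filtered trace; excursions
closer than 200 ms merge; width is the supra-threshold full width
(bounds 1–100 ms); reported amplitude is the signed raw-EEG peak.

## fEPSP / LTP

Amplitude is |negative peak − pre-stimulus baseline mean| with the
baseline over 5 ms before the stimulus; samples within 1 ms after the
stimulus are excluded everywhere (artifact / fiber volley). Clipped
traces (≥ 5 samples pinned at the extreme) are flagged. The slope is an
ordinary least-squares fit of the raw samples between the 10 % and 40 %
crossing *times* of the smoothed (3-point median) trace — fitting a
contiguous time window rather than per-sample membership in a depth
window, because membership selected on noisy values biases the slope
toward zero. The I/O plateau is the maximum observed response
(non-monotone curves warn); fractional intensities are linear
interpolations. LTP normalizes every post-induction slope to the
baseline mean (= 100 %) and reports early/late window means; the
windows default to 0–30 and 30–60 min (the figure-legend convention; the
methods text contains a duplicated "0–30 min" and records 40 min of
post-induction data, so window bounds are explicit arguments). The
canonical theta-burst schedule validator encodes 5 trains x 10 bursts x
4 pulses = 200 pulses.

## Co-expression pipeline

**Preprocessing.** Pseudobulk = summed single-cell counts per biological
sample (the sample, not the cell, is the replicate). log2CPM uses
pseudocount 1, mapping zero counts to zero. Filtering is sequential:
housekeeping names out (Rpl/Rps/mt-/Hist prefixes), genes below the 10th
MAD percentile out (zero-MAD genes always out — they carry no
co-expression signal and break correlations), then the top 5,000 genes
by log2CPM variance (variance, not MAD, for the final ranking; the
source is silent on the measure).

**Network.** Unsigned adjacency |cor|^β (the referenced tool's default;
signed vs unsigned is not stated in the source). β is the smallest power
on a 1–20 grid whose scale-free fit R² reaches 0.8, else the grid
maximum; published per-cell-type powers (24/14/14/7) can be supplied as
overrides. TOM follows the standard formula with unit diagonal. Modules:
average-linkage clustering of 1 − TOM, cut at a fraction of the tree
height mapped from the deepSplit granularity ({0: 0.98 … 4: 0.80}*,
grounded in measured within-module (≤ 0.7) versus between-module
(≥ 0.94) TOM distances on planted data), minimum module size, then
iterative merging of modules whose eigengene correlation dissimilarity
(signed 1 − cor, so anti-correlated modules stay separate) is below the
merge cut height. Leftover genes are grey. *deepSplit 1: 0.92 cut; note
a height cut is a deliberate simplification of adaptive dynamic tree
cutting — modules whose latent patterns correlate strongly (r ≳ 0.6) may
occasionally merge at deepSplit 1; deepSplit 2 separates them reliably
on planted data.

**Eigengenes.** ME = leading right singular vector (unit norm over
samples) of the gene-standardized module submatrix. kME = Pearson(gene,
ME). Sign alignment flips ME and kME together so corr(ME, mean of top-50
|kME| hub genes) > 0; the operation is an involution on aligned input,
and an exactly-zero orientation leaves the sign unchanged with a
warning. Hub genes: top 25 by |kME|, ties broken lexicographically
(random tie-breaks are forbidden for reproducibility). WT-centering
subtracts the WT mean and divides by either the WT SD (contribution
analysis) or the SD pooled within genotypes (effect-size heatmaps);
zero-variance divisors are floored at machine epsilon and flagged, which
keeps contribution *ratios* exact in noiseless closed-form cases.

**Contribution decomposition.** On WT-centered MEs, d_g(module) =
|mean_g − mean_WT| for g in {E4, NLF, E4NLF}; per-module shares
normalize the three shifts to 1 (modules with all-zero shifts are
excluded from the share table, not the totals); cell-type proportions
normalize the module-summed totals. The grey module is excluded from
both the ANOVA aggregation and the contribution totals (the source
states the exclusion only for the former; consistency argues for both).
Neuronal-vs-glial comparisons use two-sided Mann-Whitney U per component
with Bonferroni correction over the three components.

**ANOVA.** Per gene, an ordinary two-factor OLS ANOVA y ~ E4 * NLF
(type-II sums of squares; with a balanced 2x2 design the types agree),
η² = SS_term / SS_total. Fisher aggregation per module and term:
X² = −2 Σ ln p on 2k df (p clipped at 1e-300), BH-FDR across modules per
term. ME contrasts fit ME ~ C(genotype) with WT reference and report
plain t-tests, BH-corrected across all module x contrast pairs — no
empirical-Bayes moderation (the source names a moderated framework; with
~26 samples per ME the moderation is minor, and the unmoderated test is
exact under normality). A constant ME short-circuits to zero effects
with p = 1.

**Export.** Edges are within-module pairs with |r| ≥ 0.3, threshold
inclusive, canonical gene_a < gene_b ordering; node attributes carry
signed kME (color) and |kME| (size), with a hub flag for the top 25.
Heatmap tables rank genes by |kME| (variance fallback), cap at 100, and
WT-center gene-wise with the SD across all samples, zero variance
guarded to one.

## Synthetic-data generators

The generators emulate the *statistical structure* each analysis
assumes, with exact ground truth — not the underlying biology.

**Motif sequences** are first-order Markov chains, one transition matrix
per genotype, vectorized across animals. Real motif sequences have
longer-range dependencies and session-level nonstationarity; passing
tests show the transition estimators and the permutation machinery are
correct, not that first-order dynamics describe real mice.

**Pseudobulk matrices**: each planted module has a per-sample latent
with mean effect_e4·e4 + effect_nlf·nlf + effect_interaction·e4·nlf (in
latent-SD units) plus Gaussian noise (default 0.3); genes load on the
latent with uniform loadings in [0.8, 1] over per-gene baselines uniform
in [2, 8] log2CPM; background genes are unit-SD Gaussian noise. With
noise 0, planted genotype means are exact, which is what makes the
closed-form contribution checks exact. No count-level sampling, library
size variation, or dropout is simulated — the co-expression stage
consumes log-scale data, and those are the operations in scope. The
neuron-vs-glia recovery condition plants interaction-only modules in
"neuron" matrices and *opposing-sign* additive modules (+δ_E4, −δ_NLF
and the mirror) in "glia" matrices: with same-sign additive effects the
combined genotype's deviation is the sum and would always dominate,
whereas opposing shifts make the combined group return toward baseline —
a sub-additive glial response that reproduces the observation that
glial change is dominated by the single genotypes. n = 7 per genotype
and noise 0.3 are the study-scale defaults.

**EEG** is additive: per-state band-limited Gaussian oscillators (delta,
theta; amplitudes ramped over 1 s at state boundaries so modulation
steps do not inject broadband clicks) over 1/f pink noise; EMG is
modulated white noise; movement is nonzero only in Wake. The default
hypnogram composition is 40 % Wake, 26 % QW, 25 % NREM, 9 % REM (REM
always entered from NREM), a realistic light-phase mouse architecture
whose state clusters also sit in the gaps between the stager's
percentile thresholds. Spindles are planted as Tukey-windowed (α = 0.25)
sinusoids — the flat envelope makes onset/offset/duration ground truth
sharp, unlike a Hann window whose measured duration is systematically
about half the planted one under any threshold detector. Planted peak
amplitude = spindle_snr x RMS of the 10–14 Hz-filtered NREM background
(the strictest in-band SNR reading; default 3). Event counts are
deterministic (round(rate x eligible time)), placements non-overlapping
with ≥ 1 s separation. Spikes are Hann-shaped 30 ms negative transients
at 8 robust SD of the background, planted during sleep only, clear of
spindles. Fourteen-day telemetry, artifacts, electrode drift and real
spindle morphology variation are not emulated; passing tests validate
the detectors' logic and calibration, not their field performance.

**fEPSP sweeps** have a 5 ms flat baseline, a 0.4 ms artifact at the
stimulus, a linear descent at the planted slope, a 0.3 ms plateau at the
planted peak (so the sampled minimum is exact), and an exponential
recovery (τ = 8 ms), sampled at 10 kHz. Noise is additive white
Gaussian.

## Problem sizes

The recovery experiments run at the study-scale defaults: 100 planted
spindles (≈ 50 min NREM at 2/min), 500 null motif datasets of 10 animals
x 10⁴ frames for permutation calibration, 100 replicates of 2 + 2 cell
types for the synergy pattern, 28-sample pseudobulk matrices of ~150
genes. These sizes give the calibration estimates standard errors of
about one percentage point and complete in about a minute on one CPU.

## Known limitations

- The height-based tree cut is cruder than adaptive dynamic tree
  cutting; strongly correlated planted modules can merge at the default
  granularity (use deepSplit ≥ 2).
- Spindle detection at in-band SNR 3 operates at its ROC knee
  (~0.91/0.91 recall/precision); per-seed values can fall slightly
  below 0.9.
- Percentile-based staging thresholds assume a mixed state composition;
  single-state recordings need explicit thresholds.
- The permutation test reports per-cell p-values without multiplicity
  correction across cells, matching the source procedure; stars on the
  delta heatmap are nominal.
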