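# Methods

`dielphase` quantifies how laboratory evolution under continuous light
perturbs the circadian output of *Synechococcus elongatus*: growth kinetics
from optical density, diel phase classification of the transcriptome,
phase-inversion detection, transcriptome similarity to clock mutants, and
single-cell reporter rhythm estimation. Every estimator is paired with a
synthetic-data generator that inverts its model, so the full pipeline is
exercisable — and falsifiable — without any external dataset.

## Growth kinetics

**Model.** Early exponential growth: OD720(t) = OD0·e^{K′t}. The effective
growth rate K′ (h⁻¹) is the slope of ln(OD720) against time; doubling time is
ln 2 / K′. Serial-passage generations per iteration are
n = log₂(OD_f) − log₂(OD_i).

**Window selection.** "Early exponential phase" is made objective: among all
contiguous windows of ≥ 5 points whose OD lies in [2·min(OD), 0.5·max(OD)],
windows with log-linear R² ≥ 0.99 are kept and the longest (earliest start on
ties) is fitted. When the band is empty because the curve spans fewer than two
net doublings, the whole curve is the single candidate; a flat curve then
reaches the slope check and raises `NonPositiveGrowthError` rather than a
window-selection error. Points with OD ≤ 0 are excluded (with a warning)
before the log transform. Slopes below 10⁻¹² h⁻¹ are treated as no growth.

**Known bias.** On curves grown deep into saturation, the R² ≥ 0.99 tolerance
admits some logistic bend, biasing K′ low by up to ~10–15%. Growth curves
intended for rate estimation should be truncated near half-saturation; the
demo pipeline samples each strain over ~5.6 doublings for this reason. On
noiseless exponential input the fit is exact to ≤ 10⁻⁹ relative error
(tested).

## Diel phase classification

**Design.** Cultures grown in 12 h light / 12 h dark cycles are sampled at
dusk of day 3 and dawn and dusk of day 4, R ≥ 2 replicates each. On the
variance-stabilized scale x = log₂(TPM + 1), the diel amplitude of gene g is

    A_g = (mean dusk3 + mean dusk4)/2 − mean dawn4.

A > 0 is a dusk peak (Class I, RpaA-activated), A < 0 a dawn peak (Class II,
RpaA-repressed).

**Standardization.** Var(A) propagates from the replicate noise σ² as
σ²·3/(2R) (two dusk means averaged, one dawn mean subtracted). The per-gene
pooled within-timepoint variance has only 3(R−1) degrees of freedom (6 at
R = 3), and a z-statistic built on it has t₆ tails: P(|t₆| > 4) ≈ 0.007,
an order of magnitude above the advertised significance of a "4 SD" filter.
We therefore squeeze per-gene variances toward a scaled-inverse-χ² prior
fitted across genes by moment matching on log variances (the moderated-t
construction; the trigamma inverse is solved by Newton iteration). With
thousands of genes the moderated statistic is approximately normal, and the
null pass rate of the z > 4 filter is ≈ 6×10⁻⁵ — the 4-SD rule then really
is a P < 0.001 filter (verified on 10⁵ planted-flat genes in the test
suite). An absolute floor of 0.05 log₂ units guards degenerate zero-variance
genes (warned when it engages).

**Calls.** Class I iff A > 0 and z ≥ z_nc, Class II iff A < 0 and z ≥ z_nc,
noncircadian (NC) otherwise; "strong circadian" iff z > z_strong and not NC.
Defaults z_nc = 2, z_strong = 4, both exposed (the NC boundary has no
canonical value; published class counts can be matched by tuning it).
Genes with mean TPM < 1 are forced to NC and excluded from strong calls —
ratios of near-zero TPMs are noise. All thresholds, the pseudocount and the
expression floor are configurable.

**Inversion.** A reference-Class II gene is inverted when its test-condition
amplitude is positive (its dawn peak collapsed below the dusk level), the
signature of nighttime repression in clock-perturbed strains; symmetrically
for Class I. The headline fraction is over reference Class II genes. A
3×3 transition table (reference class × test class) is also reported.

## Single-cell rhythm estimation

**Model.** Each cell's fluorescence is fitted, for every candidate period T
on a grid (default 16–32 h in 0.05 h steps, restricted to periods with ≥ 2
full cycles in the trace span and below the Nyquist limit), with

    y(t) = a + b·t + β_c·cos(2πt/T) + β_s·sin(2πt/T).

The linear drift is estimated **jointly** with the oscillation: detrending
first and fitting after biases the period whenever the cosine has nonzero
covariance with time over a finite window (we measured up to 0.35 h of bias
on noiseless shifted cosines; the joint fit is exact). The
residual-minimizing T wins; amplitude is √(β_c² + β_s²) and phase the peak
time in [0, T).

**Rhythmicity call.** F-test of the cosinor against the trend-only model,
with the minimum p over the grid Bonferroni-corrected by the grid size
(321 periods). A calibration pilot showed that correcting only by the
~2.25 independent Fourier frequencies in the band leaves a ~2% false-positive
rate at the nominal 1%; the full-grid correction is conservative
(0/2000 null traces flagged) and costs nothing in practice, since
circadian-strength signals reach p-values tens of orders of magnitude below
the corrected threshold (a planted rhythm with amplitude equal to the noise
SD is still detected in 100% of cells). A second guard requires the fitted
amplitude to reach 5% of the detrended-trace SD. Cells tracked < 48 h
(two circadian cycles) are excluded from population summaries.

**Population summary.** Mean and SD (ddof = 1) of periods over rhythmic
cells; fraction rhythmic; with a reference trace set, the amplitude fold is
the ratio of median fitted amplitudes (rhythmic cells where available). A
population with no rhythmic cells is flagged arrhythmic and its period left
undefined.

## Transcriptome comparison

**Fold-change calls.** log₂FC is the difference of mean log₂(TPM + 1)
between conditions. The per-gene pooled variance is squeezed with the same
empirical-Bayes machinery as the classifier, and the t-statistic uses
df = pooled df + prior df. This is deliberate: with 3 replicates an
unmoderated two-sample test has ≈ 4 degrees of freedom and cannot reach
p < 10⁻⁸ at any effect size, so the stringent adjusted-p cutoff customary
for count-model DE tools would never fire. Information sharing across genes
is exactly what those tools do with dispersions. Benjamini–Hochberg
adjustment; calls at |FC| ≥ 1.5 and adjusted p < 10⁻⁸ (both configurable).
This is a structural stand-in for a negative-binomial count model, adequate
for direction/correlation claims, not for count-level inference.

**Repression profiles.** r_g = log₁₀((TPM_ref + 1)/(TPM_test + 1)) on
replicate-mean TPMs; genes below 1 TPM mean in the reference are excluded.
Profile similarity is plain Pearson correlation over shared retained genes.
The top-k report ranks by descending r_g (ties: ascending gene id) and
cross-checks each top gene for ≥ 5-fold repression (r ≥ log₁₀ 5) in a second
profile.

## Synthetic data: what it emulates, what it does not

* **Diel matrices** plant class structure on log₂(TPM + 1): Class I genes sit
  `amplitude_log2` above baseline at both dusks, Class II at dawn, NC flat;
  noise is additive Gaussian on the log scale (multiplicative log-normal on
  TPM), matching the classifier's variance stabilization. Inverted mode
  plants dawn = baseline − amplitude for Class II (nighttime repression).
  Defaults (2159/428/128 genes, amplitude 2.0, noise SD 0.25, baselines
  log-uniform on [2, 12], R = 3) reproduce the scale of a real diel
  transcriptome; the replicate noise SD is a calibration choice — real
  designs do not report it — so tests conditioned on it establish estimator
  correctness under the stated model, not the field noise level.
* **Traces** are cosine + trend + Gaussian noise with per-cell phase jitter
  (SD 0.5 h) around release into continuous light; defaults (amplitude 100,
  baseline 500, noise 5 a.u., 72 h at 0.5 h) emulate presynchronized
  reporter movies. Real traces have cell division artifacts, bleaching
  nonlinearity and lineage correlation that the generator does not model.
* **Profiles** are bivariate normal with the requested correlation —
  adequate for testing correlation recovery, silent about heavy tails of
  real fold-change distributions.
* **Growth curves** are exponential or logistic
  (OD = S/(1 + ((S − OD0)/OD0)e^{−K′t}), exact exponential limit S → ∞)
  with log-normal noise (`noise_sd` ≈ relative SD).

Generators are bitwise deterministic given their seed; one master seed can
drive all stages via distinct derived substreams. Truth tables carry one row
per gene/cell (class, signed amplitude, planted standardized amplitude,
inversion flag; period, amplitude, phase, rhythmic flag).

## Numerical choices

* Pseudocount 1 TPM everywhere a log of TPM is taken.
* Variance floor 0.05 (log₂ SD) in the classifier; 10⁻¹² h⁻¹ slope floor in
  the growth fit; R² defined as 1 for flat windows (zero residual and zero
  variance).
* Tie-breaks: growth windows by earliest start; top-k genes by ascending id;
  cosinor period by first grid point reaching the minimum RSS.
* Matrix TSVs round-trip byte-identically: parsing uses numpy's correctly
  rounded string→float conversion (pandas' fast parser can be off by one
  ulp).

## Limitations

* Three timepoints support only a dusk/dawn phase dichotomy; no continuous
  phase estimation or harmonic regression.
* The moderated-t comparison is not a count model; dispersion–mean trends of
  real RNA-seq counts are not represented.
* The rhythm caller assumes a single stationary period per cell; period
  drift and amplitude decay are not modeled.
* The growth-window rule is objective but admits logistic bend near
  saturation (see above).
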