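# dielphase

Quantitative analysis of circadian output in cyanobacterial evolution
experiments: growth kinetics from OD720 curves, diel transcriptome phase
classification with a strong-circadian amplitude statistic, phase-inversion
detection between strains, repression-fold correlation against clock-mutant
transcriptomes, and single-cell reporter rhythm quantification. A
planted-truth synthetic-data generator backs every stage, so the whole
pipeline runs and is tested without external data.

Intended for microbial chronobiology and experimental-evolution labs working
with *Synechococcus elongatus*-style designs: serial-passage evolution under
continuous light, diel (12 h light / 12 h dark) RNA-seq sampling at
dusk/dawn/dusk, and time-lapse fluorescence of clock-output promoter fusions.

## The statistics at the core

* **Growth.** K′ = slope of ln OD720(t) over an objectively selected early
  exponential window; doubling time t_d = ln 2 / K′; passage generations
  n = log₂(OD_f) − log₂(OD_i).
* **Diel phase.** On x = log₂(TPM+1), the amplitude of gene g is
  A_g = (x̄_dusk3 + x̄_dusk4)/2 − x̄_dawn4. Its standardized form
  z_g = |A_g| / SE(A_g) uses an empirical-Bayes moderated replicate variance,
  so the "strong circadian" rule z > 4 is a calibrated P < 10⁻³ filter even
  with three replicates. Sign of A gives the class: dusk peak (Class I,
  RpaA-activated) or dawn peak (Class II, RpaA-repressed). A reference
  Class II gene whose test-condition A turns positive has inverted its phase.
* **Rhythms.** Per cell, cosinor least squares y = a + bt +
  β_c cos(2πt/T) + β_s sin(2πt/T) over a period grid (16–32 h, 0.05 h);
  rhythmic iff the F-test against the trend-only model survives Bonferroni
  correction over the grid and the amplitude is non-negligible.
* **Comparison.** log₂ fold changes with moderated-t + Benjamini–Hochberg
  (calls at |FC| ≥ 1.5, adjusted p < 10⁻⁸); repression folds
  r_g = log₁₀((TPM_ref+1)/(TPM_test+1)); Pearson similarity between
  profiles; top-k most-repressed genes with a ≥ 5-fold cross-check.

Details, defaults and known limitations: [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
import dielphase as dp

# growth: fit a noiseless curve generated at K' = 0.4332 /h
curve = dp.gen_growth_curve(kprime=0.4332, od0=0.01, t_grid=np.arange(0, 14, 0.25))
fit = dp.fit_growth_rate(curve)
print(f"K' = {fit.kprime:.4f} /h, doubling time = {fit.doubling_time:.3f} h")

ref = dp.fit_growth_rate(dp.gen_growth_curve(np.log(2)/12.07, 0.01, np.arange(0, 96, 0.5)))
print(f"rate increase vs reference: {dp.percent_rate_increase(fit, ref):.1f}%")

# diel classification at realistic scale with planted truth
cfg = dp.SimConfig(seed=1, n_genes_per_class={"I": 2159, "II": 428, "NC": 128},
                   amplitude_log2=2.0, noise_sd_log2=0.25)
m, truth = dp.gen_diel_matrix(cfg)
calls = dp.classify_phase(m)
print("class counts:", dp.class_counts(calls))
print("strong circadian:", dp.class_counts(dp.strong_circadian_filter(calls)))

# single-cell rhythms
ts, _ = dp.gen_trace_set(n_cells=30, period_h=23.8, noise_sd=5.0, seed=3)
pop = dp.population_rhythm(ts)
print(f"period = {pop.mean_period:.2f} +/- {pop.sd_period:.3f} h, "
      f"fraction rhythmic = {pop.fraction_rhythmic:.2f}")

# transcriptome similarity with a planted correlation
p1, p2 = dp.gen_correlated_profiles(2500, rho_target=0.89, seed=7)
print(f"Pearson r = {dp.correlate_profiles(p1, p2).pearson_r:.3f}")
```

prints

```
K' = 0.4332 /h, doubling time = 1.600 h
rate increase vs reference: 654.3%
class counts: {'I': 2163, 'II': 434, 'NC': 118}
strong circadian: {'I': 2159, 'II': 428, 'NC': 0}
period = 23.81 +/- 0.027 h, fraction rhythmic = 1.00
Pearson r = 0.887
```

The doubling time and percentage come straight from the fitted slopes; the
strong-circadian filter recovers exactly the planted 2159 Class I and 428
Class II genes at this amplitude/noise ratio, while a handful of flat genes
drift over the weaker class boundary (hence 2163/434 raw counts); the
population period is the planted 23.8 h within the 0.05 h grid resolution;
the profile correlation recovers the planted ρ = 0.89 within sampling error.

## Command line

Each subcommand is a thin wrapper over the library:

```sh
dielphase simulate --out sim/ --seed 1            # matrices + traces + truth
dielphase growth   --in curve.csv --out fit.json
dielphase classify --in matrix.tsv --z-nc 2 --z-strong 4 --out calls.tsv
dielphase rhythm   --in traces.csv --ref ref_traces.csv --out rhythm.json
dielphase compare  --test evolved.tsv --ref wt.tsv --check drpaa.tsv --out cmp/
dielphase report   --config run.yaml --out run/   # full synthetic pipeline
```

Matrix TSVs have a `gene_id` column plus `condition:timepoint:replicate`
columns (timepoints `dusk3`, `dawn4`, `dusk4`); traces are
`cell_id,time_h,fluorescence` CSVs; growth curves are `time_h,od720` CSVs.
`report` reads a flat YAML config (every threshold and simulation knob has a
default) and writes stage tables plus a deterministic `report.json`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the package's reference quantity from scratch: it simulates ten
noiseless single-cell traces at angular frequency 0.26403 rad/h (72 h,
0.5 h sampling), runs the cosinor period search, and reports the population
mean period in hours as JSON.
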