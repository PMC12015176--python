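# chronolfp

Circadian chronophysiology profiling of chronically recorded local field
potentials (LFPs) from two simultaneously monitored brain regions — the
suprachiasmatic nucleus (SCN, the master circadian pacemaker) and the
nucleus accumbens (NAc) — in wild-type versus clock-deficient
(*Cry1/2*-knockout) mice under light–dark (LD) and constant-darkness (DD)
regimens.

The package is for electrophysiologists and chronobiologists who want to
turn multi-day telemetry traces (500 Hz) into a quantitative 24-hour
profile: how rhythmic each spectral band is, how fragmented the day's
activity is, how tightly the two regions co-fluctuate and in which
direction information flows, and how regular each band's time course is.

## What it computes

Raw traces are high-pass filtered at 0.5 Hz (zero-phase Butterworth),
screened for >1 mV artifacts, and decomposed per 4-s bin into ten canonical
bands tiling 0.5–70 Hz (delta 0.5–4 … gamma2 48–70 Hz). On the binned,
z-scored series the pipeline measures:

- **Rhythmicity** — the single-harmonic cosinor
  `y(t) = b0 + bs·sin(2πt/24) + bc·cos(2πt/24)` fitted by OLS; amplitude
  `√(bs²+bc²)` and acrophase (ZT of the fitted maximum), plus circular
  phase summaries, and a Lomb–Scargle periodogram (2–36 h) whose global
  maximum gives each series' dominant period and its deviation from 24 h.
- **Fragmentation** — binarize to ±1000 about zero, 250-bin right-aligned
  rolling mean, re-binarize; the number of constant runs ("blocks") counts
  alternations between high and low activity.
- **Oscillatory events** — Morlet continuous wavelet transform (7 cycles);
  bouts above a 1.96 threshold against an AR(1) red-noise background, and
  per-frequency events above the 98th power percentile with duration,
  inter-event interval and relative power.
- **Coupling** — Pearson correlations and day/night band-pair matrices,
  sign-concordance counts per 3-h window, cross-/autocorrelation at 1-s
  lags with four-lag-bin averages, Welch magnitude-squared coherence in
  108-s bins, and Granger-causality F tests in both directions.
- **Similarity/regularity** — timepoint-matched Euclidean distances between
  labelled series with binary-variable pair grouping, slope-magnitude
  histograms with skewness, sample entropy (m=2, r=0.2·SD), PCA over bands
  with within-group PC1/PC2 pair distances, and a fold-change summary of
  every measure against the wild-type/LD group.
- **Statistics** — pooled-variance t, Type II two-way ANOVA, Wilcoxon and
  two-sample KS tests, OLS regression, and exact noncentral-t sample-size
  computation.

A seeded synthetic-data generator produces two-region recordings with the
statistical structure these analyses assume (circadian band-power
modulation, two-state activity blocks, AR(1) noise, lagged inter-region
coupling, band-limited bursts) together with ground truth for parameter
recovery.

## Worked example

```python
from chronolfp.synthetic import preset_config, simulate_region_pair
from chronolfp.rhythm import CircadianHarmonicModel
from chronolfp.preprocess import zscore_values

cfg = preset_config("wildtype", "LD")          # 24 h, 4-s bins, tau = 24 h
pair = simulate_region_pair(cfg, seed=42)
gamma1 = pair["scn"].band("gamma1")
model = CircadianHarmonicModel(zscore_values(gamma1.values), gamma1.zt_hours)
print(model.fit().summary())
```

```
Circadian harmonic (cosinor) fit
  period       : 24.00 h
  n            : 21600
  intercept    : 6.72077e-17
  beta_sin     : -0.590023
  beta_cos     : -0.730747
  amplitude    : 0.939211
  peak ZT      : 14.595 h
  residual SD  : 0.747624
```

The z-scored gamma1 series carries a strong 24-h rhythm (amplitude ≈ 0.94
z-units; a noise-free sinusoid would give √2 ≈ 1.41) peaking near ZT 15,
in the dark phase where the preset places the acrophase (ZT 16; block
switching and AR(1) noise shift and damp individual fits). A
`cry_ko`/`DD` preset gives amplitudes near zero and a higher block count.

The same battery is scriptable from the shell:

```bash
chronolfp simulate --genotype wildtype --regimen LD --duration-h 24 --seed 1 --out-dir run/
chronolfp rhythm --in run/scn_bandpower.csv --out run/rhythm.csv
chronolfp blocks --in run/scn_bandpower.csv --out run/blocks.csv
chronolfp report --seed 1 --n-animals 5 --out-dir bundle/
```

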