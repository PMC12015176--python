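# Methods

## Scope and data model

The package profiles chronic two-region LFP recordings over the 24-hour day.
Its in-memory containers are a raw voltage trace (`RawTrace`, mV, uniform
sampling), a binned scalar series (`BinnedSeries`: band power, RMS
amplitude, or z-units), and a bins × bands matrix (`BandPowerSeries`) over
the ten canonical bands tiling 0.5–70 Hz. Band edges are half-open
`[lo, hi)` with the top band closed at 70 Hz, so the ten band powers sum
exactly to the total 0.5–70 Hz periodogram power of each bin (Parseval-
consistent one-sided scaling). Zeitgeber time (ZT) is hours since lights-on;
bin timestamps are left edges, so a 24-h epoch runs ZT 0 to 24 in
`24·3600/bin_s` bins (21 600 at 4 s).

## Preprocessing

- **High-pass** 0.5 Hz, 4th-order Butterworth applied forward–backward
  (zero phase). Only the cutoff is physiologically meaningful; order and
  zero-phase application are implementation choices made for a flat
  passband and no phase distortion.
- **Artifacts**: contiguous excursions of |v| > 1 mV are counted and
  masked; any bin overlapping a masked sample is dropped rather than
  interpolated (removal fabricates no data). More than 30 excursions raises
  a warning flag; a trace whose total 0.5–70 Hz power is below a
  configurable floor is flagged for exclusion (flat, contentless signal).
- **Band decomposition**: per-bin rectangular-window periodogram; a taper
  is selectable but off by default, as the plain FFT of each bin is the
  simplest defensible reading of per-bin spectral decomposition. A bin must
  be at least `2/f_lo` of the lowest band (4 s for delta at 0.5 Hz); 1-s
  binning is therefore reserved for amplitude and simulated band series.
- **Amplitude** is per-bin RMS. Vendor exports do not document their
  "amplitude"; RMS is the scale-covariant default.
- **Spectral AUC** of a binned 24-h series integrates |DFT coefficient|
  over the frequency index by the trapezoid rule, DC included (the DC term
  carries the series mean; excluding it is a one-flag change).

## Oscillatory events

Morlet wavelets with 7 cycles: the Gaussian envelope SD in time is
`n_cycles/(2πf)`, wavelets truncated at 5σ, L2-normalized, applied by FFT
convolution on a log-spaced grid (2–120 Hz, 12 voices/octave). Cells within
√2·σ_t of either edge fall inside the cone of influence and are excluded
from thresholds and detection.

Two detectors:

1. **Red-noise bouts.** The power plane is whitened by the theoretical
   AR(1) spectrum whose lag-1 coefficient is estimated from the analyzed
   segment, then calibrated globally to unit mean over valid cells. The
   *amplitude* (square root of whitened power) is thresholded at 1.96 —
   for Gaussian noise the whitened amplitude is Rayleigh with unit RMS, so
   1.96 passes ≈2% of null cells, a 95%-style criterion. The bout count per
   frequency is the number of maximal suprathreshold runs. Note that run
   *counts* are not monotone in signal strength: a very strong sustained
   oscillation merges runs, so bout-count local maxima can flank rather
   than sit on a strong oscillation's center frequency, within the wavelet
   bandwidth (±f/n_cycles).
2. **Percentile events.** Per frequency row, the threshold is the row's
   empirical 98th percentile (valid cells only), guaranteeing a ≈2%
   suprathreshold fraction by construction and making counts invariant
   under rescaling the trace. Events are temporal local maxima above
   threshold; duration is the containing suprathreshold run, interval the
   gap to the next event in the row, relative power the peak over the row
   median. Constant rows yield no events rather than an error.

Peak-frequency identification smooths bout counts with a replicate-padded
3-point mean and takes strict interior local maxima, ties broken toward the
lower frequency.

## Rhythmicity

The cosinor model `y = b0 + bs·sin(2πt/T) + bc·cos(2πt/T)` (T = 24 h) is
exposed as a model/results pair (`CircadianHarmonicModel().fit()`), with
amplitude `√(bs²+bc²)` and acrophase at the fitted maximum — identical
definitions for a single harmonic. On a z-scored noise-free sinusoid the
amplitude is √2, since z-scoring rescales a sinusoid's peak by 1/RMS.

Acrophases are summarized on the 24-h circle: mean direction of the
resultant vector, circular SD `√(−2 ln R̄)`, and a display arrow of length
1/SD capped at a configurable maximum (identical phases give SD 0). A
resultant length of ~0 leaves the mean undefined and flagged.

The Lomb–Scargle periodogram is evaluated on a uniform *period* grid,
2–36 h in steps of `0.4/oversample` h (0.1 h at the default oversampling
of 4), normalized by `N·var/2` so a noise-free sinusoid scores 1. The
dominant period is the global maximum regardless of amplitude, and
`deviation_24h = |period − 24|`. The natural localization limit is one step
of the classical frequency grid mapped to period units,
`p²/(span·oversample)` (≈2 h at 24 h over a 72-h record); the fine period
grid is for readout, not resolution, and `PeriodogramResult.
period_resolution()` exposes the honest limit. A span of at least 4/3 of
the longest requested period is required.

## Fragmentation

Z-scored series are binarized to ±1000 about zero, smoothed with a
right-aligned 250-bin rolling mean (the first 249 outputs summarize
incomplete windows and are dropped), and re-binarized; the block count is
the number of maximal constant runs. Exact zeros map to +1000 at both
stages — a deterministic tie rule needed because balanced windows roll to
exactly zero; the rolling sum is computed in integers before division so
this zero is exact. Block counts fall as dwell times lengthen
(rank correlation < −0.9 across a dwell sweep in the test suite).

## Coupling

- Cross-/autocorrelation uses the classical global-moment normalization
  (divide by N and the two full-series SDs); the value at lag ℓ is
  `corr(A_t, B_{t+ℓ})`, so positive lags mean A leads. The ±60 s profile is
  averaged in four bins, [−60,−30], [−29,−1], [+1,+29], [+30,+60] s; lag 0
  belongs to neither sign and is excluded.
- Magnitude-squared coherence: each 6-min window is split into three 108-s
  bins overlapping by 36 s; within each bin Welch estimation with 2-s Hann
  sub-segments at 50% overlap (single-segment coherence is identically 1,
  so sub-segmentation is mandatory); the three bins are averaged.
- Granger causality: for each direction an F test of the restricted
  (own lags) versus unrestricted (own + other's lags) OLS models, default
  order 1 (configurable; the appropriate order is data-dependent). The
  implementation is cross-checked against statsmodels'
  `grangercausalitytests` in the test suite.
- The day/night band-pair matrix holds ZT 0–12 correlations in the upper
  triangle and ZT 12–24 in the lower; the ten same-band SCN×NAc cells per
  half-day feed group comparisons.

## Similarity and regularity

- The timepoint-matched Euclidean distance sums the per-timepoint 2-D
  distance between two aligned series; with matched time grids the
  x-difference vanishes and the measure reduces to `Σ|Δy|` (an L1 distance
  and a pseudometric). Per-band matrices are averaged elementwise; pairs
  are grouped by any binary label into both-first-level / mixed /
  both-second-level.
- Slopes are magnitudes `|y_{i+1}−y_i|/dt` (displayed ranges are
  nonnegative); skewness is the population moment estimator `m₃/m₂^{3/2}`,
  undefined (flagged) when all slopes coincide.
- Sample entropy uses the field-standard m = 2, r = 0.2·SD, Chebyshev
  distance, self-matches excluded; the blocked vectorized count equals the
  naive O(N²) double loop exactly, which the tests assert at N = 1000.
  A constant series returns 0 with a degenerate-tolerance flag; zero
  matches at either length return infinity, flagged.
- PCA is column-centered, unscaled SVD (bins are observations, bands
  variables), matching the default of the standard PCA routine in the
  original analysis environment. Within-group PC1/PC2 pairwise distances
  are compared by a two-sample KS test. Caveat: all-pairs distances are
  dependent, so that KS test is anticonservative under the null (~46%
  rejections at α = 0.05 in a 20-point-per-group simulation); the package
  computes the procedure as defined but the p-values should be read as
  descriptive.
- Fold changes divide each group's pooled mean by the wild-type/LD mean;
  values below 1 are reported as their reciprocal with an explicit
  "decrease" flag, so the table shows magnitudes of change with direction
  annotated rather than signed ratios.

## Statistics

Student (pooled-variance) t rather than Welch, appropriate for the equal
group sizes the design prescribes. Type II two-way ANOVA (each main effect
adjusted for the other, interaction last) via statsmodels, verified against
an explicit nested-OLS oracle. "Paired Wilcoxon rank-sum" is accepted as an
alias of the signed-rank test with a warning, since a paired rank-sum test
is a contradiction in terms. Wilcoxon variants use exact enumeration for
n ≤ 8. Sample-size determination inverts the exact noncentral-t power
function; at effect size d = 2, power 0.9, α = 0.05 (two-sample,
two-sided) the smallest adequate group is n = 7, consistent with a
five-animal floor (the normal approximation gives 6.4 before small-sample
correction).

## Synthetic generator

Band power follows
`x_f(t) = M_f·(1 + A_f·cos(2π(t−φ_f)/τ))·g(t) + ε_t`, clipped at 0:

- multiplicative circadian and block terms preserve nonnegativity and make
  fragmentation scale with activity level;
- `g(t)` alternates between 1 and a low:high ratio (default 0.5) with
  exponential dwell times — memoryless, so one parameter per state
  controls the block statistic;
- `ε` is stationary AR(1); `noise_sd` is the *marginal* SD (innovations
  scaled by √(1−ρ²)), so the configured σ is directly the series SD.

Presets encode the study conditions: wild-type/LD τ = 24 h, relative
amplitude 0.6, dwell 7200 s; wild-type/DD τ = 24.3 h (free-running slightly
long), amplitude halved; knockout/LD light-driven (τ = 24 h, amplitude as
WT/DD) with 1800-s dwells; knockout/DD arrhythmic (amplitude 0) with 900-s
dwells. Mesors follow a 1/√f profile over band centers, acrophase ZT 16
(dark-phase peak), ρ = 0.5, σ = 0.25·M. Quantitative knockout event-rate
parameters are not established, so the presets encode the qualitative
ordering only.

The NAc is `w·scn(t−L) + (1−w)·η(t)` with η an independent realization of
the same marginal model (defaults w = 0.7, L = 8 s). Raw traces are
1/f-shaped Gaussian background plus Poisson-timed, lognormal-duration,
Hann-windowed sinusoidal bursts at configurable center frequencies (preset:
8.3 and 66.8 Hz), amplitudes riding the circadian envelope. A burn-in of
max(coupling lag, 100 bins) is simulated and discarded, so returned series
are stationary, start at ZT 0 and have exactly the advertised length.

What the generator does *not* emulate: non-exponential bout structure,
state-dependent spectra beyond a scalar multiplier, cross-frequency
coupling, electrode drift, or light-masking transients. Tests passing on
synthetic data therefore validate the *measurement* pipeline under its own
model assumptions, not biological claims about real recordings.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible
(seed-sequence spawning per region and band). The bundled measure battery
runs four groups × five animals × two regions × ten bands on 24-h, 4-s-bin
series; within the battery, sample entropy is computed after re-binning to
48-s bins (N = 1800) — the preset dwell times (≥900 s) are far above the
re-bin width, so the regularity ordering between genotypes is unchanged
while the O(N²) template count stays light. The direction-of-effect check
aggregates 20 seeded replicates of that battery. The acceptance script
mirrors these sizes.

## Known limitations

- EDF I/O is a minimal 16-bit implementation (integer sampling rates,
  whole-second records); it round-trips within quantization and is read
  correctly by mne, but does not cover the full EDF+ specification.
- The Lomb–Scargle dominant period of noisy circadian data is localized
  only to the natural resolution (~2 h at 24 h on 72-h records); reported
  0.1-h readout precision should not be mistaken for accuracy.
- Granger tests assume approximate stationarity; strongly rhythmic 24-h
  series violate this, which is why the battery applies them to z-scored,
  detrended segments and reports order-1 results by default.
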