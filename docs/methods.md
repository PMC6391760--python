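# Methods note

This note records the generative model behind `volecall`'s synthetic
distress calls, the measurement conventions, the numerical choices, and
the known limitations. The package reproduces a classic bioacoustic
workflow — call synthesis, spectrogram measurement, and parent-species
discriminant statistics — for three groups of red-backed voles: the Tien
Shan vole, the bank vole, and their F1 hybrids.

## 1. Generative model of call parameters

Each group is described by a `SpeciesProfile` holding the published group
mean and standard error of five parameters: call duration, maximum
fundamental frequency (f0max), frequency-modulation range, 50% energy
quartile (q50) and spectral entropy. Per-call values are drawn
independently from normal distributions with SD reconstructed as
`SE × √n_reference` (n = 118 Tien Shan, 108 hybrid, 78 bank calls), then
truncated to physical validity:

- duration ≥ 2 ms; f0max ≥ 300 Hz;
- modulation range clipped to [0, 0.95 × f0max];
- q50 in [200, 10 000] Hz; entropy in [0.01, 0.99].

Harmonic counts are uniform on [3, 10]. Each call is assigned a structure
class (harmonic / mixed / noise) from a per-group categorical mix; the
class proportions are not published, so the defaults put roughly 43% of
calls in the voiced classes overall — consistent with the reported
degrees of freedom of the fundamental-frequency ANOVAs — with bank voles
noisiest.

**Limitations of the draw.** Parameters are drawn independently: no
cross-parameter covariance is modelled, because only marginal means and
SEs are published. Truncation biases the realised modulation-range mean
upward of the nominal mean by roughly 100–200 Hz for groups whose
distribution has substantial mass below zero; population-recovery checks
therefore target duration, f0max, q50 and entropy, not modulation range.

## 2. Waveform synthesis

A call is rendered at 22 050 Hz as a mix of a harmonic stack and shaped
noise:

- **f0 contour**: a half-sine (∩-shaped) arch from `f0max − mod_range`
  up to `f0max` and back; phase is the cumulative sum of the
  instantaneous frequency.
- **Harmonic stack**: partials k·f0 with a Gaussian amplitude rolloff
  (width one partial index) centred on `q50_target / f0max`, so the
  energy centroid lands near the drawn q50. Partials reaching 98% of the
  Nyquist frequency are dropped.
- **Shaped noise**: white noise spectrally masked by a Gaussian of width
  2.5 kHz centred on the q50 target, with an amplitude floor of 0.5
  across the band up to 0.97 × Nyquist so noise calls have genuinely
  broadband energy (otherwise the geometric mean — and with it the
  entropy — collapses).
- **Mixing**: harmonic and noise components are combined by energy
  fraction. The `noise_fraction` of mixed calls is set from the drawn
  entropy target through a fixed monotone calibration anchored at the
  measured entropy of a pure-harmonic call (≈ 0.05) and a pure-noise call
  (≈ 0.62) at study-typical durations.
- An attack/decay envelope (10% / 20% of duration) and a low-level
  broadband background (RMS 4% of the call) complete the signal.

**What the generator does not emulate**: amplitude modulation within the
call, nonlinear phenomena (subharmonics, deterministic chaos, biphonation),
inter-call variation of the noise band centre independent of q50, or any
recording-channel effects. Entropy targets above ≈ 0.62 cannot be reached
by the mixing model; such calls saturate near the pure-noise value.

## 3. Spectrogram and measurements

All measurements use a Hamming-windowed 512-point FFT with 87.5% overlap
(hop 64 samples). At 22 050 Hz this gives a frequency resolution of
about 43 Hz per bin; the frame hop is ≈ 2.9 ms, finer than the nominal
time resolution quoted for the reference analysis settings (which is
internally inconsistent with its own overlap figure; we follow the
overlap).

- **Duration**: −20 dB threshold on the smoothed (1 ms boxcar) amplitude
  envelope. The smoothing spills ≈ 0.5 ms per side, so durations of
  silence-padded versus unpadded signals can differ by up to ~1 ms.
- **Call-average power spectrum**: mean per-bin power over frames whose
  energy exceeds 1% of the loudest frame.
- **Peak frequency**: arg-max bin (ties break to the lowest frequency).
- **Energy quartiles**: the first bin at which the cumulative power
  reaches 25 / 50 / 75% of the total.
- **Spectral entropy**: geometric mean over arithmetic mean of the
  per-bin power — exactly 1 for a flat spectrum, → 0 for a single bin.
- **Fundamental tracking**: per-frame comb search over 800–6000 Hz in
  10 Hz steps scoring the mean log-power at the first five partials
  (partials above Nyquist contribute the spectrum's median log-power as
  a penalty), with parabolic refinement; frames whose within-±1-bin
  partial power fraction ("harmonicity") falls below 0.25 are unvoiced.
  f0max is the track maximum and the modulation range its span.
- **Structure typing**: the voiced-frame fraction of a call — ≥ 0.8
  harmonic, ≤ 0.2 noise, otherwise mixed.

**Known measurement limitations.** The comb tracker's contract is the
0.8–6 kHz band: trajectories that dip below 800 Hz can alias to an
upper harmonic and inflate f0max. Fast modulation smears partials across
the 512-point window, depressing harmonicity; with the default profiles
this under-counts voiced calls relative to the nominal structure mix
(mostly Tien Shan calls, whose 2.5 kHz arch in 27 ms is the fastest
sweep). Frequencies quantise to the 43 Hz bin grid.

## 4. Statistics

- One-way fixed-effects ANOVA with Tukey HSD (α = 0.05); Kruskal–Wallis
  plus the grand-median test with Bonferroni-adjusted pairwise rank-sum z
  for peak frequency.
- Two-group linear DFA from the pooled within-group covariance with
  **equal priors** (the legacy desktop-statistics convention). A relative
  ridge of 1e−8 × trace is applied only if the pooled covariance is
  near-singular. Reported: resubstitution percent correct, confusion
  matrix, Wilks' Λ and one-feature-removed partial Λ, split-half
  (stratified) cross-validation, and a label-permutation chance level
  (default 100 permutations; for 118/78 groups with uninformative
  features this lands near 53–55% — above 50% because resubstitution on
  permuted labels retains a small optimism bias).
- Chi-squared comparison of attribution percentages via the
  reconstructed 2×2 correct/incorrect table (Yates correction by
  default).
- **Hybrid placement**: each animal's mean feature vector is placed by
  squared Mahalanobis distance to both parent centroids under the pooled
  within-parent covariance. A hybrid is "intermediate" when, on both
  parent axes, its distance exceeds the parents' own median
  self-distance but stays below the other parent's median distance.
  With the default profiles the hybrids' q50 (≈ 7.9 kHz) exceeds both
  parents' (4.0 / 6.8 kHz), so hybrids typically plot *beyond* the bank
  centroid rather than between the parents — they are nearer the bank
  vole but not flagged intermediate. This transgressive q50 is a feature
  of the published group means, not an artefact of the generator.

## 5. Reproducibility

Every stochastic stage takes an explicit seed (master default 20190226);
per-call synthesis seeds are drawn from the master stream, and
`report.json` is byte-identical across runs of the same configuration.
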