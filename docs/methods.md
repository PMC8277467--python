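# Methods

## Physical model and assumptions

A vocalization emitted at planar position **x** at time *t* reaches station
*pᵢ* after travelling `‖x − pᵢ‖ / v`, where *v* is a single constant
wavespeed for the medium (air or ground). All stations are treated as lying
in one horizontal plane and as sharing a GPS-synchronized clock, so the
time difference of arrival between the reference station *p₀* (defined as
the station with the strongest signal, in practice the first arrival) and
station *pᵢ* is

```
τᵢ = (‖x − pᵢ‖ − ‖x − p₀‖) / v .
```

Each τᵢ constrains **x** to one branch of a hyperbola with foci *p₀*, *pᵢ*.
Four stations give three independent TDOAs. The model deliberately excludes
elevation, heterogeneous or direction-dependent wavespeed fields, multipath
and dispersion; these are real effects in the field but outside the scope of
the constant-wavespeed estimators implemented here.

## Signal processing

**Stacking.** Multi-channel records (e.g. a four-microphone station) are
summed sample-wise: coherent signal amplitude grows with the channel count
*n* while independent noise power grows only with *n*, improving SNR by √n.

**Spectrograms.** Magnitude STFT with a Hann window. Defaults: window 0.5 s,
overlap 0.9 (hop 0.05 s), frequencies truncated above 100 Hz (the flat-
response limit of broadband seismometers; nothing above it carries rumble
energy). A 3–5 s call then spans 60–100 time columns — enough to resolve the
frequency contour. Acoustic records are resampled to a common 400 Hz
analysis rate (polyphase, anti-aliased) before the STFT so both modalities
share the same time resolution; the original audio rate carries no useful
information above the truncation band.

**Enhancement.** The spectrogram is log-compressed (`log1p`, so gradients are
not dominated by the loudest pixels), smoothed with a Gaussian of
`gradient_scale` bins (default 1), and differentiated. The per-pixel outer
product of the gradient is smoothed at `integration_scale` bins (default 3)
to form the structure tensor, with eigenvalues λ₁ ≥ λ₂ ≥ 0. The coherence

```
c = ((λ₁ − λ₂) / (λ₁ + λ₂ + ε))^exponent ,    ε = 1e-12
```

is ≈1 on oriented ridges (one dominant gradient direction) and ≈0 on
isotropic texture. Each pixel is weighted by `max(c, floor)` with floor 0.05
so faint but structured signal is never erased entirely. The net effect is
that frequency contours survive while broadband noise is attenuated by up to
1/floor. Enhancement never changes the image shape or axes and cannot
produce negative magnitudes.

## TDOA estimation

Two spectrograms are cross-correlated along the time axis: the score at an
integer bin lag ℓ is the cosine similarity (inner product over the
overlapping columns divided by the product of the sub-images' Frobenius
norms) of the two non-negative images. Cosine normalization bounds scores in
[0, 1] and makes the lag invariant to amplitude scaling — station gains
differ and carry no timing information. The search is restricted to
|ℓ| ≤ 1.5 × (array diameter / 200 m/s): no physical TDOA can exceed the
inter-station travel time at the slowest plausible wavespeed, and bounding
the search suppresses spurious side peaks.

The peak lag is refined below one bin by parabolic interpolation through the
three samples around the maximum; on noise-free synthetic scenes this
recovers lags to ~0.1 ms, i.e. ~0.2 % of a bin. Absolute window start-time
offsets between stations are added to convert bin lags to true TDOAs.

**Quality gate.** Correlation quality is judged by the *topographic
prominence* of the global peak — its height above the higher of the two
outer minima flanking it (the lowest enclosing contour line) — rather than
by the correlation value itself, which a uniformly high noise floor
depresses without making the peak less usable. An event is rejected, naming
the failing station pair, if any pair's prominence falls below
`min_prominence` (default 0.1; the threshold is a config knob because usable
values depend on site noise).

Candidate event windows are supplied by the user (catalogue CSV or CLI
timestamps); automated call detection is deliberately out of scope.

## Localization

**Deterministic.** For each wavespeed on a grid of guesses (defaults:
acoustic 320–380 m/s step 5 — air speed varies little; seismic
200–1500 m/s step 25 — near-surface ground speeds vary widely), the source
position is fitted by Levenberg–Marquardt least squares on the lag
mismatches with an analytic Jacobian, multi-started from a 3×3 grid over the
position prior box because hyperbola intersections are non-convex. Each grid
wavespeed yields one candidate estimate.

**Probabilistic.** The posterior over (x, y, v) — or (x, y, v_seis, v_acou)
for the joint bimodal model, which multiplies both modalities' likelihoods
while sharing the position — is

```
p(θ | τ) ∝ prior(x) · prior(v) · Π_i N(τᵢ | τᵢ(θ), σ²)
```

with a uniform position prior (station bounding box padded 200 m), uniform
wavespeed priors, and σ (`tdoa_sigma`) defaulting to one spectrogram time
bin, the dominant known lag error for quantized correlation peaks. Sampling
uses an affine-invariant ensemble sampler (32 walkers, ≥4000 post-burn-in
samples, fixed seed). Walker initialization adapts to how informative the
likelihood is, judged from an importance-weighted prior cloud: near-flat
likelihoods start the walkers as prior draws (already stationary); weakly
concentrated ones start them on the highest-density draws, which trace the
position–wavespeed ridge; needle-sharp ones (σ → 0) locate the mode by local
optimization and size a Gaussian ball from the local curvature. After
sampling, the best sample is polished into the exact maximum-a-posteriori
point by Nelder–Mead and appended, so the sample set always contains the
MAP.

**Residual and selection.** Every candidate (grid point or posterior sample)
is scored by

```
residual = v · mean_i |observed τᵢ − predicted τᵢ(x, v)|      [metres]
```

and the minimum-residual candidate is the reported location. (A mean lag
mismatch *divided* by a wavespeed would have units of s²/m; multiplying by
*v* is the dimensionally consistent way to express the mismatch in metres,
and is what this package computes.) The same residual is used for both
solvers and, pooled over both modalities' pairs, for the joint model.

**A caution on identifiability.** With four stations there are three TDOAs
and three free parameters, so the system is exactly determined: for generic
observed lags an (x, v) exists that reproduces them *exactly*, and the
residual of the best candidate is then a measure of search granularity, not
of data quality. Two consequences, both visible in the Monte-Carlo suites:

* *Noise amplification.* Because the fit can interpolate the observations,
  lag noise propagates into position error amplified by the local geometry
  rather than being averaged down; position errors several times the
  per-lag equivalent distance (v · σ_lag) are normal, and the
  position–wavespeed ridge (a faster wave from farther away predicts nearly
  the same TDOAs) stretches errors further when the wavespeed search range
  is wide.
* *Ghost solutions.* The exactly determined system can admit more than one
  root within a generous search region — a second position at a different
  wavespeed that reproduces the same TDOAs. Root searches on synthetic
  scenes show such ghosts for a substantial fraction of source positions.
  The minimum-residual rule cannot distinguish a ghost from the true
  source; only external knowledge (a tighter wavespeed prior, more
  stations, or a second modality) can.

For this reason the synthetic acceptance studies report both the noise-free
behaviour (sub-decimetre recovery) and the degraded behaviour under
half-a-time-bin lag noise (median errors of tens of metres), rather than
suggesting the method's field accuracy is a single number.

## Synthetic scenes

The generator emulates the target deployment: four stations up to ~360 m
apart around a central source region (the shipped layout in
`default_station_layout` / `data` fixtures is synthetic — real deployment
coordinates are not public), a call of duration 3–5 s (default 4 s) whose
fundamental rises 22→38 Hz and falls back (piecewise-linear contour,
phase-continuous by integrating the instantaneous frequency, 5 % cosine
tapers), and per-medium propagation:

* delay `d/v` applied spectrally (exact for band-limited signals),
  amplitude × 1/max(d, 1);
* seismic (default 400 m/s): 8th-order Butterworth-magnitude low-pass at
  45 Hz applied zero-phase, strong enough that harmonics are effectively
  absent from seismic spectra, as observed in the field;
* acoustic (default 350 m/s): the microphone's low-frequency roll-off
  interpolated in dB over frequency (−10 dB at 20 Hz, −4 dB at 40 Hz,
  −2 dB at 50 Hz, flat from 100 Hz), so acoustic correlation rests mostly
  on the harmonics.

Noise is additive white Gaussian (optionally band-limited 10–90 Hz), scaled
so the RMS signal-to-noise ratio at the *nearest* station equals the target
SNR — farther stations are relatively noisier, as in the field. Seismic
records are generated at 200 Hz; acoustic records default to 4410 Hz, which
preserves everything below the analysis band while keeping scenes cheap
(the rate is configurable; nothing above the 400 Hz analysis rate survives
decimation anyway). `simulate_tdoa_set` provides a waveform-free shortcut —
geometric TDOAs plus Gaussian lag noise — for large repeated-trial studies
of the solvers alone.

What the generator does **not** emulate: multipath and reflections,
topography, wind and non-stationary noise, wavespeed heterogeneity and
dispersion, overlapping calls from multiple animals, and clock drift.
Passing tests on synthetic scenes therefore demonstrate the correctness of
the processing chain and its behaviour under the modelled error sources,
not field performance in complex terrain.

## Numerical choices

* Least squares: MINPACK Levenberg–Marquardt, analytic Jacobian, tolerances
  1e-12; 9 multistarts per wavespeed; non-convergent grid points are
  flagged on the estimate, not dropped.
* Correlation sub-bin refinement: parabolic, clipped to ±half a bin;
  degenerate (non-concave) neighbourhoods fall back to the grid peak.
* Structure tensor: `ε = 1e-12` guards the coherence quotient; coherence is
  clipped to [0, 1] before exponentiation.
* Prominence of the global peak uses the outer-minima definition directly;
  interior secondary peaks use the standard topographic algorithm.
* Ties in minimum-residual selection break to the first candidate
  (deterministic: grid order; probabilistic: sample order).
* All samplers and noise draws are seeded; identical configuration and seed
  reproduce outputs bit-for-bit (timestamps aside).

## Tunable parameters

| parameter | default | unit | role |
|---|---|---|---|
| `window_length_s` | 0.5 | s | STFT window |
| `overlap` | 0.9 | – | STFT overlap (hop 0.05 s) |
| `f_max_hz` | 100 | Hz | spectrogram truncation |
| `analysis_rate_hz` | 400 | Hz | common acoustic resample rate |
| `enhancement.gradient_scale` | 1 | bins | pre-gradient smoothing |
| `enhancement.integration_scale` | 3 | bins | tensor smoothing |
| `enhancement.exponent` | 1 | – | coherence sharpening |
| `enhancement.floor` | 0.05 | – | minimum pixel weight |
| `max_lag_s` | 1.5·D/200 | s | correlation search bound |
| `min_prominence` | 0.1 | – | event acceptance gate |
| `tdoa_sigma_s` | one time bin | s | TDOA likelihood width |
| wavespeed grid (acoustic) | 320–380 step 5 | m/s | deterministic sweep |
| wavespeed grid (seismic) | 200–1500 step 25 | m/s | deterministic sweep |
| position prior | array box + 200 m | m | uniform prior / multistart box |
| `n_samples` | 4000 | – | post-burn-in MCMC samples |

## Known limitations

* Constant wavespeed per medium; no 3-D, no heterogeneity.
* Minimal-data geometry (four stations) makes the free-wavespeed inversion
  exactly determined — see the identifiability caution above. Denser arrays
  would restore redundancy.
* The correlation stage assumes the same call shape at all stations;
  strong station-dependent filtering or overlapping calls will bias lags.
* Event windows are user-supplied; there is no automated call detector.
* Waveform I/O is WAV plus a JSON metadata sidecar; binary seismological
  container formats are not read.
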