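# rumbleloc

Seismo-acoustic localization of low-frequency animal vocalizations by
time-difference-of-arrival (TDOA) multilateration.

African elephant rumbles radiate simultaneously through the air (~350 m/s,
fundamental plus harmonics) and through the ground (~400 m/s, fundamental
only — the ground acts as a low-pass filter). A small array of
GPS-synchronized seismometers and microphones can therefore locate a
vocalizing animal from either wave type. `rumbleloc` implements the full
processing chain for researchers in wildlife monitoring and bioacoustics who
deploy such arrays:

1. **Signal** — multi-channel stacking, STFT magnitude spectrograms
   truncated to the band of interest, and structure-tensor image
   enhancement that amplifies anisotropic frequency contours (the rumble's
   rising-then-falling 20–40 Hz ridge) while damping isotropic noise.
2. **TDOA** — normalized cross-correlation of enhanced spectrograms along
   the time axis between a reference station *p₀* (the strongest signal)
   and every other station *pᵢ*, with sub-bin lag refinement and a
   peak-prominence quality gate that rejects unusable events.
3. **Localization** — each TDOA constrains the source to a hyperbola
   `v · (tᵢ − t₀) = ‖x − pᵢ‖ − ‖x − p₀‖`; with four stations the source
   position **x** is estimated by
   * a **deterministic** solver: multi-start nonlinear least squares over
     **x** for every wavespeed *v* on a grid of guesses, and
   * a **probabilistic** solver: affine-invariant ensemble MCMC over
     (**x**, *v*) with Gaussian TDOA likelihood, including a **joint**
     bimodal variant that shares one position between the seismic and
     acoustic TDOA sets with independent wavespeeds.

   Every candidate solution is scored by the residual
   `r = v · mean_i |observed lagᵢ − predicted lagᵢ|` (metres), and the
   minimum-residual candidate is the reported location.
4. **Metrics** — summary statistics over per-event residual tables
   (means, s.d., cross-method Pearson correlations, seismic-vs-acoustic win
   counts) and the interaural-delay arithmetic that maps wavespeeds to the
   arrival-time differences available across a listening animal's ears.
5. **Synthetic scenes** — a ground-truthed simulator (harmonic-stack chirp
   source, per-medium propagation filters, 1/r decay, sub-sample delays,
   additive noise at a target SNR) so the entire chain is testable without
   field recordings.

## Worked example

Simulate a four-station scene with a rumble at (25, 10) m and SNR 10 at the
nearest station, estimate seismic TDOAs, and localize:

```python
import rumbleloc as rl
from rumbleloc.io import RunConfig, event_window_from_waveforms
from rumbleloc.tdoa import build_tdoa_set, default_max_lag
from rumbleloc.geometry import station_array

cfg = RunConfig()
stations = rl.default_station_layout()
scene = rl.generate_scene(stations=stations, source=(25.0, 10.0), snr=10.0, seed=42)

win = event_window_from_waveforms(scene.waveforms, "demo", 0.0, 1e9, "seismic", cfg)
tdoas = build_tdoa_set(win, default_max_lag(station_array(stations)),
                       cfg.min_prominence, modality="seismic")
model = rl.TdoaLocationModel(tdoas, stations, cfg.solver_config())
print(model.fit().summary())
```

which prints

```
Deterministic TDOA localization
  modality        : seismic
  station pairs   : 3
  wavespeed grid  : 53 guesses
  best wavespeed  : 400.0 m/s
  best position   : (24.93, 10.05) m
  best residual   : 0.026 m
```

The rumble was most pronounced at station ETA, so ETA became the reference;
the three correlation peaks (prominences ≈ 0.86) gave lags of +0.018, +0.033
and +0.116 s to the other stations. The grid sweep recovers the true
wavespeed (400 m/s) and the source to within 9 cm; the 0.026 m residual
means the best position reproduces the measured TDOAs to an equivalent
distance of 2.6 cm averaged over station pairs. `model.fit_probabilistic()`
returns posterior samples over (x, y, v) whose minimum-residual sample lands
at (24.89, 10.04) m — note the *posterior spread* is large because with only
three TDOAs, position trades off against wavespeed along a ridge; the
summary table of a fitted `ProbabilisticResults` shows both.

The same chain is available from the shell:

```bash
rumbleloc simulate --seed 42 --snr 10 --out scene/
rumbleloc run --data scene/ --out results/ --modality both --method both
rumbleloc summarize results/residual_table.csv
```

## Layout

```
src/rumbleloc/
  signal.py     waveforms, spectrograms, structure-tensor enhancement
  tdoa.py       spectrogram correlation, prominence gating, TDOA sets
  locate.py     deterministic + Bayesian multilateration models
  metrics.py    residual-table statistics, interaural delays
  synth.py      synthetic scene generator (ground truth included)
  io.py         stations/catalogue/config I/O and the event pipeline
  cli.py        `rumbleloc` command-line interface
docs/methods.md   model, assumptions, parameter choices, limitations
```
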