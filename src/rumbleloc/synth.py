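"""Synthetic seismo-acoustic scenes with known ground truth.

Emulates the field situation the package targets: four co-located
seismo-acoustic stations (aperture up to ~360 m) around a source region, a
low-frequency call of 3-5 s whose fundamental rises then falls between 20
and 40 Hz, and two propagation paths from the same source --

* acoustic: ~350 m/s, carries the fundamental plus harmonics, shaped by the
  microphone's low-frequency roll-off (-10 dB at 20 Hz, -4 dB at 40 Hz,
  -2 dB at 50 Hz, flat from 100 Hz);
* seismic: ~400 m/s, the ground acts as a low-pass filter so only the
  fundamental survives (default cutoff 45 Hz).

Propagation is single-path with 1/r geometric amplitude decay and no
dispersion, matching the constant-wavespeed assumption of the solvers.
Additive white (optionally band-limited) Gaussian noise is scaled to a
target SNR at the nearest station.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .geometry import StationGeometry, station_array
from .locate import predict_tdoas
from .signal import Waveform
from .tdoa import TdoaSet

__all__ = [
    "RumbleSpec",
    "SyntheticScene",
    "synthesize_call",
    "propagate",
    "generate_scene",
    "simulate_tdoa_set",
    "random_source_in_hull",
    "default_station_layout",
]

MIC_ROLLOFF_DB = ((0.0, -30.0), (20.0, -10.0), (40.0, -4.0), (50.0, -2.0), (100.0, 0.0))


@dataclass
class RumbleSpec:
    """Shape of one synthetic call.

    ``f0_contour`` is a piecewise-linear path of (time fraction, Hz) control
    points, rising then falling within [20, 40] Hz.  Acoustic harmonics k
    carry amplitude ``harmonic_decay**(k-1)``.
    """

    duration: float = 4.0
    f0_contour: tuple = ((0.0, 22.0), (0.5, 38.0), (1.0, 22.0))
    n_harmonics_acoustic: int = 3
    harmonic_decay: float = 0.5
    source_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 3.0 <= self.duration <= 5.0:
            raise ValueError(f"duration must be in [3, 5] s, got {self.duration}")
        freqs = np.array([f for _, f in self.f0_contour])
        if np.any(freqs < 20.0) or np.any(freqs > 40.0):
            raise ValueError("f0 contour must stay within [20, 40] Hz")
        if self.n_harmonics_acoustic < 1:
            raise ValueError("need at least one harmonic")

    def f0(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous fundamental at times t (s from call onset)."""
        pts = np.asarray(self.f0_contour, dtype=float)
        return np.interp(t / self.duration, pts[:, 0], pts[:, 1])


@dataclass
class SyntheticScene:
    """Ground truth plus the per-station synthetic records."""

    stations: list[StationGeometry]
    true_source: np.ndarray
    v_acoustic: float
    v_seismic: float
    snr: float | None
    rng_seed: int
    spec: RumbleSpec
    emit_time: float
    waveforms: dict = field(default_factory=dict)  # (station_id, modality) -> Waveform

    def waveform(self, station_id: str, modality: str) -> Waveform:
        return self.waveforms[(station_id, modality)]

    def true_tdoas(self, modality: str, reference: str) -> np.ndarray:
        v = self.v_seismic if modality == "seismic" else self.v_acoustic
        return predict_tdoas(self.true_source, self.stations, reference, v)

    def ground_truth_dict(self) -> dict:
        return {
            "true_source": self.true_source.tolist(),
            "v_acoustic": self.v_acoustic,
            "v_seismic": self.v_seismic,
            "snr": self.snr,
            "rng_seed": self.rng_seed,
            "emit_time": self.emit_time,
            "duration": self.spec.duration,
        }


def synthesize_call(spec: RumbleSpec, rate: float, n_harmonics: int | None = None) -> Waveform:
    """Phase-continuous harmonic stack with a 5% cosine taper at each edge.

    The instantaneous frequency of harmonic k is k * f0(t); phases come from
    integrating f0 so the contour is glitch-free.  Raises if any harmonic
    would cross the Nyquist frequency.
    """
    nh = spec.n_harmonics_acoustic if n_harmonics is None else n_harmonics
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    f0 = spec.f0(t)
    if nh * f0.max() >= rate / 2:
        raise ValueError(
            f"harmonic {nh} of {f0.max():.0f} Hz exceeds Nyquist ({rate / 2:.0f} Hz)"
        )
    phase = 2.0 * np.pi * np.cumsum(f0) / rate
    x = np.zeros(n)
    for k in range(1, nh + 1):
        x += spec.harmonic_decay ** (k - 1) * np.sin(k * phase)
    x *= spec.source_amplitude * sps.windows.tukey(n, alpha=0.1)
    return Waveform(samples=x, sampling_rate=rate, modality="acoustic")


def _gain_profile(freqs: np.ndarray, modality: str, seismic_cutoff: float) -> np.ndarray:
    """Zero-phase |gain| over frequency for each propagation medium."""
    if modality == "seismic":
        # 8th-order Butterworth magnitude: the ground low-pass is strong
        # enough that harmonics are effectively absent from seismic spectra
        return 1.0 / np.sqrt(1.0 + (freqs / seismic_cutoff) ** 16)
    pts = np.asarray(MIC_ROLLOFF_DB)
    db = np.interp(freqs, pts[:, 0], pts[:, 1], left=pts[0, 1], right=0.0)
    return 10.0 ** (db / 20.0)


def propagate(
    call: Waveform,
    distance: float,
    v: float,
    modality: str,
    seismic_cutoff: float = 45.0,
) -> Waveform:
    """Delay, attenuate and filter a call over one source-station path.

    The delay distance/v is applied spectrally (a phase ramp), so sub-sample
    delays are exact for band-limited signals; amplitude scales as
    1/max(distance, 1) m; the medium filter is applied zero-phase in the
    same transform.
    """
    if v <= 0:
        raise ValueError("wavespeed must be > 0")
    if distance < 0:
        raise ValueError("distance must be >= 0")
    rate = call.sampling_rate
    delay = distance / v
    n_in = call.n_samples
    n_out = n_in + int(np.ceil(delay * rate)) + int(rate)  # headroom against wrap
    x = np.zeros(n_out)
    x[:n_in] = call.samples[0]
    freqs = np.fft.rfftfreq(n_out, d=1.0 / rate)
    spec = np.fft.rfft(x)
    spec *= _gain_profile(freqs, modality, seismic_cutoff)
    spec *= np.exp(-2j * np.pi * freqs * delay)
    y = np.fft.irfft(spec, n=n_out) / max(distance, 1.0)
    return replace(call, samples=np.atleast_2d(y), modality=modality)


def default_station_layout() -> list[StationGeometry]:
    """Four-station ring around a central source region (synthetic layout).

    A slightly irregular ~320 m-aperture quadrilateral; the real deployment
    coordinates are not public, so these are stand-ins with the same scale.
    """
    return [
        StationGeometry("ETA", 162.0, 12.0, "both"),
        StationGeometry("NTA", -18.0, 148.0, "both"),
        StationGeometry("STA", 20.0, -140.0, "both"),
        StationGeometry("WTA", -155.0, -25.0, "both"),
    ]


def generate_scene(
    stations: list[StationGeometry] | None = None,
    source: np.ndarray | tuple = (25.0, 10.0),
    spec: RumbleSpec | None = None,
    v_acoustic: float = 350.0,
    v_seismic: float = 400.0,
    snr: float | None = None,
    seed: int = 0,
    acoustic_rate: float = 4410.0,
    seismic_rate: float = 200.0,
    pre_s: float = 2.0,
    post_s: float = 2.0,
    band_limited_noise: bool = False,
) -> SyntheticScene:
    """Build a full scene: per-station seismic and acoustic records.

    The call is emitted at ``pre_s`` seconds into every record; all records
    share start_time 0 on the common (GPS-like) clock and are long enough to
    contain every arrival.  ``snr`` is the RMS signal-to-noise amplitude
    ratio at the *nearest* station (farther stations are noisier in relative
    terms, as in the field); ``snr=None`` means noise-free.
    """
    stations = stations if stations is not None else default_station_layout()
    spec = spec or RumbleSpec()
    source = np.asarray(source, dtype=float)
    rng = np.random.default_rng(seed)
    xy = station_array(stations)
    dists = np.linalg.norm(xy - source, axis=1)
    v_min = min(v_acoustic, v_seismic)
    total = pre_s + spec.duration + dists.max() / v_min + post_s

    scene = SyntheticScene(
        stations=stations,
        true_source=source,
        v_acoustic=v_acoustic,
        v_seismic=v_seismic,
        snr=snr,
        rng_seed=seed,
        spec=spec,
        emit_time=pre_s,
    )
    for modality, rate, v, nh in (
        ("seismic", seismic_rate, v_seismic, 1),
        ("acoustic", acoustic_rate, v_acoustic, spec.n_harmonics_acoustic),
    ):
        call = synthesize_call(spec, rate, n_harmonics=nh)
        n_total = int(round(total * rate))
        offset = int(round(pre_s * rate))
        arrivals = {}
        for st, d in zip(stations, dists):
            arr = propagate(call, float(d), v, modality)
            rec = np.zeros(n_total)
            seg = arr.samples[0][: n_total - offset]
            rec[offset : offset + seg.size] = seg
            arrivals[st.station_id] = rec
        if snr is not None:
            nearest = stations[int(np.argmin(dists))].station_id
            sig_rms = float(np.sqrt(np.mean(arrivals[nearest] ** 2)))
            sigma = sig_rms / snr
            for sid in arrivals:
                noise = rng.normal(0.0, sigma, n_total)
                if band_limited_noise:
                    sos = sps.butter(4, [10.0, min(90.0, rate / 2 * 0.95)], "bandpass",
                                     fs=rate, output="sos")
                    noise = sps.sosfiltfilt(sos, noise)
                    noise *= sigma / max(np.std(noise), 1e-30)
                arrivals[sid] = arrivals[sid] + noise
        for st in stations:
            scene.waveforms[(st.station_id, modality)] = Waveform(
                samples=arrivals[st.station_id],
                sampling_rate=rate,
                start_time=0.0,
                station_id=st.station_id,
                modality=modality,
            )
    return scene


def random_source_in_hull(
    stations: list[StationGeometry], rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Uniform random source position inside the station array's convex hull."""
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    xy = station_array(stations)
    tri = Delaunay(xy)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    for _ in range(10000):
        p = rng.uniform(lo, hi)
        if tri.find_simplex(p) >= 0:
            return p
    raise RuntimeError("could not sample a point inside the array hull")


def simulate_tdoa_set(
    stations: list[StationGeometry],
    source: np.ndarray | tuple,
    v: float,
    sigma_lag: float = 0.0,
    rng: np.random.Generator | int | None = None,
    modality: str = "seismic",
    event_id: str = "",
) -> TdoaSet:
    """Geometric TDOAs plus Gaussian lag noise -- the fast Monte-Carlo path.

    Skips waveform synthesis and correlation entirely: the reference is the
    station nearest the source (the first arrival) and each observed lag is
    the geometric TDOA perturbed by N(0, sigma_lag**2).  Used for large
    repeated-trial studies of the solvers where the correlation stage is not
    under test.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    source = np.asarray(source, dtype=float)
    xy = station_array(stations)
    dists = np.linalg.norm(xy - source, axis=1)
    ref = stations[int(np.argmin(dists))].station_id
    order = [s.station_id for s in stations if s.station_id != ref]
    lags = predict_tdoas(source, stations, ref, v, order=order)
    lags = lags + rng.normal(0.0, sigma_lag, lags.size)
    pairs = [(sid, float(lag), 1.0) for sid, lag in zip(order, lags)]
    return TdoaSet(reference_station=ref, pairs=pairs, modality=modality, event_id=event_id)
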