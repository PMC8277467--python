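"""Time-difference-of-arrival estimation by spectrogram cross-correlation.

For each event a reference station (the one where the call is most
pronounced) is correlated against every other station by sliding the two
enhanced spectrogram images past each other along the time axis.  The lag
of the correlation peak, refined below one time bin by parabolic
interpolation, is the TDOA for that station pair; the topographic
prominence of the peak is the quality measure used to accept or reject the
event -- prominence rather than the raw correlation value, because a
sharply defined peak survives high noise floors that depress all
correlation scores uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .signal import Spectrogram

__all__ = [
    "CorrelationCurve",
    "TdoaSet",
    "EventWindow",
    "select_reference_station",
    "correlate_pair",
    "peak_prominence",
    "build_tdoa_set",
    "EventRejected",
]


class EventRejected(ValueError):
    """An event failed a selection criterion (named in the message)."""


@dataclass
class CorrelationCurve:
    """Normalized correlation score as a function of time lag.

    ``peak_lag`` is the sub-bin-refined lag of the global maximum; positive
    lag means the *other* station's signal arrives later than the
    reference's.
    """

    lags: np.ndarray
    values: np.ndarray
    peak_lag: float
    peak_prominence: float
    bin_step: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.size != self.values.size or self.lags.size == 0:
            raise ValueError("lags and values must be equal-length, non-empty")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class TdoaSet:
    """Per-pair TDOAs of one event against a reference station."""

    reference_station: str
    pairs: list[tuple[str, float, float]]  # (station id, lag s, prominence)
    modality: str = "seismic"
    event_id: str = ""

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.pairs]
        if self.reference_station in ids:
            raise ValueError("reference station cannot appear among pair targets")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pair station ids")
        if not all(np.isfinite(p[1]) for p in self.pairs):
            raise ValueError("lags must be finite")

    @property
    def station_ids(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def lags(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=float)

    @property
    def prominences(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=float)

    def to_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "modality": self.modality,
            "reference": self.reference_station,
            "pairs": [
                {"station": s, "lag_s": lag, "prominence": prom}
                for s, lag, prom in self.pairs
            ],
        }


@dataclass
class EventWindow:
    """Enhanced per-station spectrograms covering one candidate call."""

    event_id: str
    spectrograms: dict[str, Spectrogram]

    def __post_init__(self) -> None:
        if not self.spectrograms:
            raise ValueError("event window holds no spectrograms")


def select_reference_station(windows: EventWindow) -> str:
    """Station with the strongest enhanced signal; lexicographic tie-break."""
    best_id, best_mag = None, -np.inf
    for sid in sorted(windows.spectrograms):
        total = float(windows.spectrograms[sid].magnitudes.sum())
        if total > best_mag:
            best_id, best_mag = sid, total
    return best_id


def _cosine_correlation(ref: np.ndarray, other: np.ndarray, max_bins: int) -> np.ndarray:
    """Normalized sliding correlation of two (freq x time) images.

    score(l) = <ref[:, a:b], other[:, a+l:b+l]> / (||ref sub|| ||other sub||)
    over the overlapping columns; cosine similarity bounds scores in [0, 1]
    for non-negative images and makes the lag invariant to amplitude scale.
    """
    n = ref.shape[1]
    scores = np.zeros(2 * max_bins + 1)
    for k, lag in enumerate(range(-max_bins, max_bins + 1)):
        if lag >= 0:
            a = ref[:, : n - lag] if lag else ref
            b = other[:, lag:]
        else:
            a = ref[:, -lag:]
            b = other[:, : n + lag]
        if a.shape[1] == 0:
            continue
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        scores[k] = float((a * b).sum() / denom) if denom > 0 else 0.0
    return scores


def _parabolic_refine(values: np.ndarray, i: int) -> float:
    """Sub-bin offset of a peak at index i from its two neighbours."""
    if i == 0 or i == values.size - 1:
        return 0.0
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a strict local max; leave on the grid
        return 0.0
    delta = 0.5 * (y0 - y2) / denom
    return float(np.clip(delta, -0.5, 0.5))


def peak_prominence(curve: CorrelationCurve | np.ndarray) -> float:
    """Topographic prominence of the curve's global maximum.

    Height of the peak above the higher of the two outer minima flanking
    it -- the level of its lowest enclosing contour line.  A flat curve has
    prominence 0.
    """
    values = curve.values if isinstance(curve, CorrelationCurve) else np.asarray(curve, float)
    if values.size == 0:
        raise ValueError("empty correlation curve")
    i = int(np.argmax(values))
    left = values[: i + 1].min() if i > 0 else values[i]
    right = values[i:].min() if i < values.size - 1 else values[i]
    return float(values[i] - max(left, right))


def secondary_prominences(values: np.ndarray) -> np.ndarray:
    """Prominences of all interior local maxima (diagnostic)."""
    peaks, _ = find_peaks(values)
    if peaks.size == 0:
        return np.array([])
    return peak_prominences(values, peaks)[0]


def correlate_pair(ref: Spectrogram, other: Spectrogram, max_lag: float) -> CorrelationCurve:
    """Cross-correlate two spectrograms along time, |lag| <= max_lag seconds.

    Requires matching frequency axes and time-bin spacing.  The returned
    ``peak_lag`` is in seconds relative to the shared window start; absolute
    start-time offsets are added by :func:`build_tdoa_set`.
    """
    if ref.freq_axis.size != other.freq_axis.size or not np.allclose(
        ref.freq_axis, other.freq_axis
    ):
        raise ValueError("frequency axes differ between the two spectrograms")
    dt_r, dt_o = ref.time_step, other.time_step
    if not np.isclose(dt_r, dt_o):
        raise ValueError(f"time-bin spacing differs: {dt_r} vs {dt_o}")
    n = min(ref.magnitudes.shape[1], other.magnitudes.shape[1])
    max_bins = max(1, int(round(max_lag / dt_r)))
    max_bins = min(max_bins, n - 1)
    scores = _cosine_correlation(ref.magnitudes[:, :n], other.magnitudes[:, :n], max_bins)
    lags = np.arange(-max_bins, max_bins + 1) * dt_r
    i = int(np.argmax(scores))
    prom = peak_prominence(scores)
    peak = lags[i] + _parabolic_refine(scores, i) * dt_r
    return CorrelationCurve(
        lags=lags, values=scores, peak_lag=float(peak), peak_prominence=prom, bin_step=dt_r
    )


def build_tdoa_set(
    windows: EventWindow,
    max_lag: float,
    min_prominence: float = 0.1,
    modality: str = "seismic",
) -> TdoaSet:
    """Correlate the reference against every other station, gated on prominence.

    The event is rejected -- with the failing pair named -- if any pair's
    correlation peak prominence falls below ``min_prominence``.  Bin lags
    are converted to true TDOAs in seconds using the spectrogram time step
    plus the absolute start-time offset between the two windows.
    """
    if len(windows.spectrograms) < 2:
        raise EventRejected(f"event {windows.event_id!r}: fewer than 2 stations")
    ref_id = select_reference_station(windows)
    ref = windows.spectrograms[ref_id]
    pairs = []
    for sid in sorted(windows.spectrograms):
        if sid == ref_id:
            continue
        other = windows.spectrograms[sid]
        curve = correlate_pair(ref, other, max_lag)
        if curve.peak_prominence < min_prominence:
            raise EventRejected(
                f"event {windows.event_id!r}: pair {ref_id}/{sid} peak prominence "
                f"{curve.peak_prominence:.3f} below threshold {min_prominence}"
            )
        lag = curve.peak_lag + (other.start_time - ref.start_time)
        pairs.append((sid, float(lag), float(curve.peak_prominence)))
    return TdoaSet(
        reference_station=ref_id, pairs=pairs, modality=modality, event_id=windows.event_id
    )


def default_max_lag(station_xy: np.ndarray, v_min: float = 200.0) -> float:
    """1.5 x (array diameter / v_min): no physical TDOA can exceed this."""
    xy = np.asarray(station_xy, dtype=float)
    d = 0.0
    for i in range(len(xy)):
        d = max(d, float(np.max(np.linalg.norm(xy - xy[i], axis=1))))
    return 1.5 * d / v_min
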