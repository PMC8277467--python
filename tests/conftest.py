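import numpy as np
import pytest

from rumbleloc.geometry import StationGeometry
from rumbleloc.io import RunConfig, event_window_from_waveforms
from rumbleloc.signal import Spectrogram, Waveform
from rumbleloc.synth import default_station_layout, generate_scene
from rumbleloc.tdoa import build_tdoa_set, default_max_lag
from rumbleloc.geometry import station_array


@pytest.fixture(scope="session")
def stations():
    return default_station_layout()


@pytest.fixture(scope="session")
def square_stations():
    return [
        StationGeometry("A", 150.0, 150.0),
        StationGeometry("B", -150.0, 150.0),
        StationGeometry("C", -150.0, -150.0),
        StationGeometry("D", 150.0, -150.0),
    ]


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def noiseless_scene(stations):
    """One noise-free scene at the generator's default central source."""
    return generate_scene(stations=stations, source=(25.0, 10.0), snr=None, seed=7)


@pytest.fixture(scope="session")
def noiseless_tdoas(noiseless_scene, stations, run_config):
    """Seismic TDOA set measured end-to-end from the noise-free scene."""
    max_lag = default_max_lag(station_array(stations))
    win = event_window_from_waveforms(
        noiseless_scene.waveforms, "fixture", 0.0, 1e9, "seismic", run_config
    )
    return build_tdoa_set(win, max_lag, run_config.min_prominence, modality="seismic")


def make_spectrogram(mags, dt=0.05, df=2.0, **kw):
    mags = np.asarray(mags, dtype=float)
    nf, nt = mags.shape
    return Spectrogram(
        magnitudes=mags,
        freq_axis=np.arange(nf) * df,
        time_axis=np.arange(nt) * dt,
        **kw,
    )


def ridge_image(nf=30, nt=80, row=12, amplitude=1.0, noise=0.0, rng=None):
    """Spectrogram-like image with one hot horizontal ridge."""
    rng = rng or np.random.default_rng(0)
    img = noise * np.abs(rng.normal(size=(nf, nt)))
    img[row] += amplitude
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
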