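"""Planar station geometry.

All localization is done in a local planar metric frame (metres, easting /
northing); stations are assumed to lie in one horizontal plane.  Geographic
coordinates must be projected externally before use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StationGeometry", "station_array", "array_bounding_box"]


@dataclass(frozen=True)
class StationGeometry:
    """One sensor site: id, planar position in metres, modality."""

    station_id: str
    x: float
    y: float
    modality: str = "both"  # seismic | acoustic | both

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def station_array(stations: list[StationGeometry]) -> np.ndarray:
    """(n, 2) array of station positions, in list order."""
    return np.array([[s.x, s.y] for s in stations], dtype=float)


def array_bounding_box(
    stations: list[StationGeometry], pad: float = 200.0
) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of the station array, padded by ``pad`` m."""
    xy = station_array(stations)
    return (
        float(xy[:, 0].min() - pad),
        float(xy[:, 0].max() + pad),
        float(xy[:, 1].min() - pad),
        float(xy[:, 1].max() + pad),
    )
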