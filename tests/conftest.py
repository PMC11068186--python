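"""Shared fixtures: tiny hand-built tracks and geometry helpers.

Latitude/longitude fixtures are built in a local metre frame around a
reference point and converted with the same equirectangular scale the
package uses, so distances in tests read directly in metres.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

REF_LAT = 42.73
REF_LON = -84.48
M_PER_DEG_LAT = 111_194.92664455873
T0 = pd.Timestamp("2022-06-15 12:00:00")


def xy_to_latlon(x, y):
    lat = REF_LAT + np.asarray(y, dtype=float) / M_PER_DEG_LAT
    lon = REF_LON + np.asarray(x, dtype=float) / (M_PER_DEG_LAT * np.cos(np.radians(REF_LAT)))
    return lat, lon


def make_track(xy, epoch_s=5, t0=T0, lux=None, start_index=0):
    """Linked-track DataFrame from a list of (x, y) metre offsets.

    ``None`` entries become missing positions (explicit gap rows).
    """
    n = len(xy)
    t = pd.date_range(t0 + pd.to_timedelta(start_index * epoch_s, unit="s"), periods=n, freq=pd.to_timedelta(epoch_s, unit="s"))
    lat = np.full(n, np.nan)
    lon = np.full(n, np.nan)
    for i, p in enumerate(xy):
        if p is not None:
            lat[i], lon[i] = xy_to_latlon(p[0], p[1])
    return pd.DataFrame(
        {
            "t": t,
            "lat": lat,
            "lon": lon,
            "axis1": 0.0,
            "axis2": 0.0,
            "axis3": 0.0,
            "lux": np.full(n, np.nan) if lux is None else np.asarray(lux, dtype=float),
            "speed_mps": np.nan,
            "source": "observed",
            "noise": False,
        }
    )


@pytest.fixture
def square_building():
    """A 20 m x 20 m building footprint centred on the reference point."""
    from shapely.geometry import Polygon

    from iotrack.geodata import PolygonLayer

    lat, lon = xy_to_latlon(np.array([-10, 10, 10, -10]), np.array([-10, -10, 10, 10]))
    return PolygonLayer("building", [Polygon(zip(lon, lat))])


@pytest.fixture
def square_park():
    from shapely.geometry import Polygon

    from iotrack.geodata import PolygonLayer

    lat, lon = xy_to_latlon(np.array([-10, 10, 10, -10]), np.array([-10, -10, 10, 10]))
    return PolygonLayer("park", [Polygon(zip(lon, lat))])
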