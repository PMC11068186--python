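"""GPS noise flagging, short-gap imputation and per-epoch speed annotation.

Raw wearable GPS has two characteristic defects this module repairs before
clustering: single-epoch "teleports" (multipath reflections that throw one
fix hundreds of metres away) and short dropouts when the receiver loses
lock indoors.  Teleports are detected by their implied speed — a fix is
noise when the speed both into and out of it exceeds ``max_speed_mps`` —
and their positions are treated as missing downstream.  Dropouts no longer
than ``max_gap_impute_s`` and bounded by observed fixes are filled by
linear interpolation of latitude/longitude against time; the 5-minute
default matches the temporal tolerance of the destination clustering so
imputed dwells stay cluster-connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessConfig",
    "haversine_m",
    "annotate_speeds",
    "flag_noise",
    "impute_gaps",
    "preprocess_track",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class PreprocessConfig:
    """Noise / imputation thresholds.

    max_speed_mps
        Implied speed above which a fix is physically implausible
        (default 40 m/s = 144 km/h, well above road speeds).
    max_gap_impute_s
        Longest dropout that is filled by interpolation (default 300 s).
    epoch_s
        Length of the analysis epoch in seconds.
    """

    max_speed_mps: float = 40.0
    max_gap_impute_s: float = 300.0
    epoch_s: float = 5.0

    def __post_init__(self) -> None:
        if min(self.max_speed_mps, self.max_gap_impute_s, self.epoch_s) <= 0:
            raise ValueError("all PreprocessConfig fields must be positive")


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres on a sphere of radius 6,371,000 m.

    Vectorised over numpy arrays / pandas Series.
    """
    la1, lo1, la2, lo2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def _positions(track: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows carrying a usable position (not missing, not noise)."""
    return track["lat"].notna() & ~track["noise"].fillna(False).astype(bool)


def annotate_speeds(track: pd.DataFrame) -> pd.DataFrame:
    """Fill ``speed_mps`` from consecutive positioned epochs.

    Epoch *i* gets the distance from epoch *i−1* divided by their time
    difference, provided both carry positions and they are adjacent rows;
    the first epoch and epochs bordering gaps keep NaN speed.
    """
    out = track.copy()
    have = _positions(out).to_numpy()
    lat = out["lat"].to_numpy(dtype=float)
    lon = out["lon"].to_numpy(dtype=float)
    t = out["t"].astype("int64").to_numpy() / 1e9
    speed = np.full(len(out), np.nan)
    if len(out) > 1:
        ok = have[1:] & have[:-1]
        d = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dt = t[1:] - t[:-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            speed[1:] = np.where(ok & (dt > 0), d / dt, np.nan)
    out["speed_mps"] = speed
    return out


def flag_noise(track: pd.DataFrame, cfg: PreprocessConfig | None = None) -> pd.DataFrame:
    """Flag teleport fixes whose implied speed is implausible in both directions.

    Speeds are computed between consecutive *positioned* fixes (skipping
    gaps, using actual time differences); a fix is flagged when the speed
    from its previous positioned neighbour and to its next positioned
    neighbour both exceed ``cfg.max_speed_mps``.  The check repeats with
    flagged fixes removed until no new flags appear, so the operation is
    idempotent.
    """
    cfg = cfg or PreprocessConfig()
    out = track.copy()
    if "noise" not in out.columns:
        out["noise"] = False
    out["noise"] = out["noise"].fillna(False).astype(bool)
    t = out["t"].astype("int64").to_numpy() / 1e9
    lat = out["lat"].to_numpy(dtype=float)
    lon = out["lon"].to_numpy(dtype=float)

    while True:
        idx = np.flatnonzero(_positions(out).to_numpy())
        if len(idx) < 3:
            break
        la, lo, tt = lat[idx], lon[idx], t[idx]
        seg = haversine_m(la[:-1], lo[:-1], la[1:], lo[1:]) / (tt[1:] - tt[:-1])
        fast_in = seg[:-1] > cfg.max_speed_mps
        fast_out = seg[1:] > cfg.max_speed_mps
        new = idx[1:-1][fast_in & fast_out]
        if len(new) == 0:
            break
        out.loc[out.index[new], "noise"] = True
    return out


def impute_gaps(track: pd.DataFrame, cfg: PreprocessConfig | None = None) -> pd.DataFrame:
    """Fill short position gaps by linear interpolation against time.

    A gap is a maximal run of epochs without a usable position bounded on
    both sides by positioned fixes; it is filled only when its duration
    (last missing tick − first missing tick + one epoch) does not exceed
    ``cfg.max_gap_impute_s``.  Filled rows get ``source="imputed"``;
    observed fixes are never altered.
    """
    cfg = cfg or PreprocessConfig()
    out = track.copy()
    have = _positions(out).to_numpy()
    idx = np.flatnonzero(have)
    if len(idx) < 2:
        return out
    t = out["t"].astype("int64").to_numpy() / 1e9
    lat = out["lat"].to_numpy(dtype=float)
    lon = out["lon"].to_numpy(dtype=float)
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a <= 1:
            continue
        gap_s = (b - a - 1) * cfg.epoch_s
        if gap_s > cfg.max_gap_impute_s:
            continue
        inner = np.arange(a + 1, b)
        frac = (t[inner] - t[a]) / (t[b] - t[a])
        out.loc[out.index[inner], "lat"] = lat[a] + frac * (lat[b] - lat[a])
        out.loc[out.index[inner], "lon"] = lon[a] + frac * (lon[b] - lon[a])
        out.loc[out.index[inner], "source"] = "imputed"
        out.loc[out.index[inner], "noise"] = False
    return out


def preprocess_track(track: pd.DataFrame, cfg: PreprocessConfig | None = None):
    """Run the full preprocessing chain: flag noise → impute gaps → speeds.

    Speeds are (re)computed after imputation so imputed fixes carry finite
    speeds.  Returns ``(track, stats)`` where ``stats`` counts flagged and
    imputed points.
    """
    cfg = cfg or PreprocessConfig()
    flagged = flag_noise(track, cfg)
    n_noise = int(flagged["noise"].sum()) - int(track.get("noise", pd.Series(False, index=track.index)).fillna(False).sum())
    imputed = impute_gaps(flagged, cfg)
    n_imputed = int((imputed["source"] == "imputed").sum())
    done = annotate_speeds(imputed)
    return done, {"noise_flagged": n_noise, "imputed": n_imputed}
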