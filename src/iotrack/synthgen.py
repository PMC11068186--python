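"""Synthetic worlds and ground-truthed tracks for pipeline testing.

Real validation data for indoor/outdoor classification — belt-worn GPS
plus accelerometer with a light sensor, annotated by activity diaries —
is rarely shareable, so this module fabricates it.  A *world* is a small
campus-like scene (rectangular buildings, one of them glass-walled, a
park, a long straight road); a *scenario* is a sequence of activity
segments emulating a two-hour wear protocol that visits each behaviour at
least once: walking and sitting indoors, walking and sitting outdoors,
and driving.

The GPS error model is deliberately simple: isotropic Gaussian jitter
(larger indoors), occasional indoor multipath excursions that throw fixes
tens of metres outside the building at high implied speed, and random
indoor dropouts.  Lux is lognormal with indoor and outdoor medians
straddling the 240-lx indoor ceiling; dwells in the glass-walled building
draw *outdoor* lux to exercise the false-positive path of the lux
correction.  Each drive includes a 90-s sub-threshold slowdown so the
bout-bridging rule is exercised.  Every epoch's true class is known by
construction and recorded in the returned diary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geodata import PolygonLayer

__all__ = [
    "Segment",
    "ScenarioConfig",
    "World",
    "SimResult",
    "make_world",
    "simulate_track",
    "default_segments",
    "sensitivity_segments",
    "low_noise_config",
]

ORIGIN_LAT = 42.73
ORIGIN_LON = -84.48
_M_PER_DEG_LAT = 111_194.92664455873
T0 = pd.Timestamp("2022-06-15 10:00:00")

MODES = ("indoor_sedentary", "indoor_active", "outdoor_sedentary", "outdoor_active", "drive")
TRUTH = {
    "indoor_sedentary": "indoor",
    "indoor_active": "indoor",
    "outdoor_sedentary": "outdoor",
    "outdoor_active": "outdoor",
    "drive": "vehicle",
}


@dataclass(frozen=True)
class Segment:
    """One diary segment of the simulated protocol.

    ``building`` picks which building an indoor segment uses; ``site``
    selects where an outdoor_sedentary bout happens ("park" or "plaza" —
    an open paved area outside any mapped polygon).
    """

    mode: str
    duration_min: float
    building: int = 0
    site: str = "park"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown segment mode {self.mode!r}")
        if self.duration_min <= 0:
            raise ValueError("segment durations must be positive")


def default_segments() -> list[Segment]:
    """The five-activity, two-hour wear protocol (drive last, so the
    track ends on the road and no long position jump follows it)."""
    return [
        Segment("indoor_active", 20, building=0),
        Segment("outdoor_sedentary", 25, site="park"),
        Segment("indoor_sedentary", 40, building=1),
        Segment("outdoor_active", 20),
        Segment("drive", 15),
    ]


def sensitivity_segments() -> list[Segment]:
    """Scenario exercising the optional filters: two short dwells only the
    building-footprint filter can catch (one in the glass-walled
    building), and a long stationary plaza bout that only the lux
    correction can rescue from the duration filters."""
    return [
        Segment("indoor_sedentary", 10, building=0),
        Segment("outdoor_active", 15),
        Segment("indoor_sedentary", 10, building=2),  # glass-walled
        Segment("outdoor_active", 10),
        Segment("outdoor_sedentary", 30, site="plaza"),
        Segment("indoor_sedentary", 30, building=1),
        Segment("drive", 15),
    ]


@dataclass
class ScenarioConfig:
    """Simulation parameters; defaults reflect consumer belt-worn devices.

    GPS jitter is ~3 m 1-sigma in the open and degrades to ~8 m indoors;
    ``indoor_drift_prob`` is the per-epoch chance of starting a multipath
    excursion; ``dropout_prob_indoor`` the per-epoch chance of losing the
    fix indoors.  Lux medians (100 lx indoors, 5000 lx outdoors) straddle
    the 240-lx classification ceiling with lognormal sigma 0.5.
    """

    seed: int = 0
    epoch_s: float = 5.0
    segments: list[Segment] = field(default_factory=default_segments)
    gps_sigma_outdoor_m: float = 3.0
    gps_sigma_indoor_m: float = 8.0
    indoor_drift_prob: float = 0.02
    dropout_prob_indoor: float = 0.05
    walk_speed_mps: float = 1.4
    drive_speed_mps: float = 12.0
    lux_indoor_mean: float = 100.0
    lux_outdoor_mean: float = 5000.0
    lux_lognormal_sigma: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.indoor_drift_prob, self.dropout_prob_indoor):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")


def low_noise_config(seed: int, segments: list[Segment] | None = None) -> ScenarioConfig:
    """A benign-conditions variant: open-sky jitter, no multipath
    excursions, rare dropouts — the regime where the classifier should
    recover the diary almost perfectly."""
    return ScenarioConfig(
        seed=seed,
        segments=segments if segments is not None else default_segments(),
        gps_sigma_outdoor_m=1.5,
        gps_sigma_indoor_m=3.0,
        indoor_drift_prob=0.0,
        dropout_prob_indoor=0.01,
    )


@dataclass
class World:
    buildings: PolygonLayer
    parks: PolygonLayer
    road: list[tuple[float, float]]  # (lat, lon) vertices
    glass: list[bool]
    building_anchors_xy: list[tuple[float, float]]
    park_anchor_xy: tuple[float, float]
    plaza_xy: tuple[float, float]
    road_start_xy: tuple[float, float]
    road_xy: list[tuple[float, float]]


def _to_latlon(x, y):
    lat = ORIGIN_LAT + np.asarray(y) / _M_PER_DEG_LAT
    lon = ORIGIN_LON + np.asarray(x) / (_M_PER_DEG_LAT * np.cos(np.radians(ORIGIN_LAT)))
    return lat, lon


def _rect(cx, cy, w, h) -> Polygon:
    xs = [cx - w / 2, cx + w / 2, cx + w / 2, cx - w / 2]
    ys = [cy - h / 2, cy - h / 2, cy + h / 2, cy + h / 2]
    lat, lon = _to_latlon(np.array(xs), np.array(ys))
    return Polygon(zip(lon, lat))


def make_world(seed: int = 0) -> World:
    """Deterministic campus scene: four buildings (index 2 glass-walled),
    one park and a 6-km straight road kept well clear of the buildings."""
    rng = np.random.default_rng(seed)
    centers = [(0.0, 0.0), (120.0, 0.0), (0.0, 120.0), (120.0, 120.0)]
    sizes = [(40, 30), (44, 32), (36, 28), (30, 24)]
    jitter = rng.uniform(-3, 3, size=(4, 2))
    buildings, anchors = [], []
    for (cx, cy), (w, h), (jx, jy) in zip(centers, sizes, jitter):
        buildings.append(_rect(cx + jx, cy + jy, w, h))
        anchors.append((cx + jx, cy + jy))
    park = _rect(-120.0, 0.0, 80, 80)
    road_xy = [(200.0, -50.0), (6200.0, -50.0)]
    road_latlon = [tuple(np.asarray(v).item() for v in _to_latlon(x, y)) for x, y in road_xy]
    return World(
        buildings=PolygonLayer("building", buildings),
        parks=PolygonLayer("park", [park]),
        road=road_latlon,
        glass=[False, False, True, False],
        building_anchors_xy=anchors,
        park_anchor_xy=(-120.0, 0.0),
        plaza_xy=(60.0, -80.0),
        road_start_xy=road_xy[0],
        road_xy=road_xy,
    )


# ---------------------------------------------------------------------------
# track simulation


def _segment_anchor(world: World, seg: Segment):
    if seg.mode.startswith("indoor"):
        return world.building_anchors_xy[seg.building]
    if seg.mode == "outdoor_sedentary":
        return world.park_anchor_xy if seg.site == "park" else world.plaza_xy
    if seg.mode == "drive":
        return world.road_start_xy
    return None  # walks end wherever the next anchor is


def _walk_path(rng, start, target, n, speed, epoch_s):
    """Walk from start to target, arriving exactly at epoch n.

    The walker takes a two-leg detour via a turn point on the ellipse
    whose foci are start and target and whose major axis equals the total
    distance walked, so the pace is constant and the path departs the
    start promptly (no lingering near buildings).  The detour side and
    angle are randomised per segment.
    """
    total = n * speed * epoch_s
    sx, sy = start
    tx, ty = target
    d = float(np.hypot(tx - sx, ty - sy))
    if total <= d + 1.0:
        frac = np.arange(1, n + 1) / n
        return sx + frac * (tx - sx), sy + frac * (ty - sy)
    a = total / 2.0
    b = float(np.sqrt(a**2 - (d / 2.0) ** 2))
    cx, cy = (sx + tx) / 2.0, (sy + ty) / 2.0
    if d > 1e-9:
        e1 = np.array([tx - sx, ty - sy]) / d
    else:
        ang = rng.uniform(0, 2 * np.pi)
        e1 = np.array([np.cos(ang), np.sin(ang)])
    e2 = np.array([-e1[1], e1[0]])
    psi = rng.uniform(np.pi / 3, 2 * np.pi / 3) * rng.choice([-1.0, 1.0])
    px, py = np.array([cx, cy]) + a * np.cos(psi) * e1 + b * np.sin(psi) * e2
    leg1 = float(np.hypot(px - sx, py - sy))  # leg1 + leg2 == total (ellipse)
    s = np.arange(1, n + 1) * speed * epoch_s
    xs = np.where(s <= leg1, sx + (px - sx) * s / leg1, px + (tx - px) * (s - leg1) / (total - leg1))
    ys = np.where(s <= leg1, sy + (py - sy) * s / leg1, py + (ty - py) * (s - leg1) / (total - leg1))
    return xs, ys


def _drive_path(world: World, n, speed, epoch_s, slow_start_s=180.0, slow_len_s=90.0, slow_speed=2.0):
    """Out-and-back along the road at constant speed with one 90-s
    sub-threshold slowdown (a long traffic light)."""
    (x0, y0), (x1, y1) = world.road_xy[0], world.road_xy[-1]
    length = float(np.hypot(x1 - x0, y1 - y0))
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    xs = np.empty(n)
    ys = np.empty(n)
    s = 0.0
    for i in range(1, n + 1):
        t = i * epoch_s
        v = slow_speed if slow_start_s <= t < slow_start_s + slow_len_s else speed
        s += v * epoch_s
        # reflect at the road ends
        period = 2 * length
        sp = s % period
        along = sp if sp <= length else period - sp
        xs[i - 1] = x0 + ux * along
        ys[i - 1] = y0 + uy * along
    return xs, ys


@dataclass
class SimResult:
    gps: pd.DataFrame      # raw fixes (with jittered timestamps, dropouts)
    acc: pd.DataFrame      # complete 5-s accelerometer epochs
    diary: pd.DataFrame    # segment start + true mode
    truth: pd.Series       # true class per grid epoch
    grid: pd.DatetimeIndex


def simulate_track(world: World, cfg: ScenarioConfig) -> SimResult:
    """Simulate one wear session over the given world.

    Returns raw GPS fixes (timestamps jittered off-grid, indoor dropouts
    removed), the complete accelerometer epoch stream, the truthful diary
    and the per-epoch ground-truth class.  Fully determined by
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    epoch_s = cfg.epoch_s
    n_total = int(round(sum(s.duration_min for s in cfg.segments) * 60 / epoch_s))
    grid = pd.date_range(T0, periods=n_total, freq=pd.to_timedelta(epoch_s, unit="s"))

    true_x = np.empty(n_total)
    true_y = np.empty(n_total)
    modes = np.empty(n_total, dtype=object)
    glass_epoch = np.zeros(n_total, dtype=bool)

    # segment layout and anchors
    bounds = np.cumsum([0] + [int(round(s.duration_min * 60 / epoch_s)) for s in cfg.segments])
    if bounds[-1] != n_total:
        raise ValueError("segment durations do not tile the track")
    anchors = [_segment_anchor(world, s) for s in cfg.segments]
    cur = anchors[0] if anchors[0] is not None else (0.0, 0.0)

    for k, seg in enumerate(cfg.segments):
        a, b = bounds[k], bounds[k + 1]
        n = b - a
        modes[a:b] = seg.mode
        if seg.mode in ("indoor_sedentary", "outdoor_sedentary"):
            cx, cy = anchors[k]
            true_x[a:b] = cx
            true_y[a:b] = cy
            cur = (cx, cy)
        elif seg.mode == "indoor_active":
            # shuffle between waypoints inside the building at a browsing pace
            cx, cy = anchors[k]
            x, y = cx, cy
            wp = (cx, cy)
            for i in range(n):
                if np.hypot(wp[0] - x, wp[1] - y) < 1.0:
                    wp = (cx + rng.uniform(-12, 12), cy + rng.uniform(-9, 9))
                ang = np.arctan2(wp[1] - y, wp[0] - x)
                x += 0.5 * epoch_s * np.cos(ang)
                y += 0.5 * epoch_s * np.sin(ang)
                true_x[a + i], true_y[a + i] = x, y
            cur = (x, y)
        elif seg.mode == "outdoor_active":
            nxt = next((anc for anc in anchors[k + 1:] if anc is not None), cur)
            xs, ys = _walk_path(rng, cur, nxt, n, cfg.walk_speed_mps, epoch_s)
            true_x[a:b], true_y[a:b] = xs, ys
            cur = (xs[-1], ys[-1])
        elif seg.mode == "drive":
            xs, ys = _drive_path(world, n, cfg.drive_speed_mps, epoch_s)
            true_x[a:b], true_y[a:b] = xs, ys
            cur = (xs[-1], ys[-1])
        if seg.mode.startswith("indoor") and world.glass[seg.building]:
            glass_epoch[a:b] = True

    indoor_epoch = np.array([m.startswith("indoor") for m in modes])

    # GPS observation model -------------------------------------------------
    sigma = np.where(indoor_epoch, cfg.gps_sigma_indoor_m, cfg.gps_sigma_outdoor_m)
    obs_x = true_x + rng.normal(0, sigma)
    obs_y = true_y + rng.normal(0, sigma)

    # indoor multipath excursions: fixes thrown outside the building
    i = 0
    while i < n_total:
        if indoor_epoch[i] and rng.uniform() < cfg.indoor_drift_prob:
            length = int(rng.integers(2, 7))
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(25, 70)
            for j in range(i, min(i + length, n_total)):
                if not indoor_epoch[j]:
                    break
                obs_x[j] = true_x[j] + dist * np.cos(ang) + rng.normal(0, 5)
                obs_y[j] = true_y[j] + dist * np.sin(ang) + rng.normal(0, 5)
            i += length
        else:
            i += 1

    dropout = indoor_epoch & (rng.uniform(size=n_total) < cfg.dropout_prob_indoor)
    keep = ~dropout
    t_jitter = rng.uniform(-1.0, 1.0, size=n_total)
    lat, lon = _to_latlon(obs_x, obs_y)
    gps = pd.DataFrame(
        {
            "t": grid[keep] + pd.to_timedelta(t_jitter[keep], unit="s"),
            "lat": lat[keep],
            "lon": lon[keep],
            "source": "observed",
            "noise": False,
        }
    ).reset_index(drop=True)

    # accelerometer stream --------------------------------------------------
    active = np.array([m in ("indoor_active", "outdoor_active") for m in modes])
    driving = modes == "drive"
    ax1 = np.where(active, rng.poisson(350, n_total), np.where(driving, rng.poisson(30, n_total), rng.poisson(8, n_total)))
    ax2 = np.where(active, rng.poisson(120, n_total), rng.poisson(6, n_total))
    ax3 = np.where(active, rng.poisson(90, n_total), rng.poisson(5, n_total))
    lux_median = np.where(indoor_epoch & ~glass_epoch, cfg.lux_indoor_mean, cfg.lux_outdoor_mean)
    # doorway effect: the first/last ~minute of a walk that borders an indoor
    # segment is spent in or at the building (corridor, lobby, entrance), so
    # those epochs draw that building's lux
    n_door = int(round(60.0 / epoch_s))
    for k, seg in enumerate(cfg.segments):
        if seg.mode != "outdoor_active":
            continue
        a, b = bounds[k], bounds[k + 1]
        if k > 0 and cfg.segments[k - 1].mode.startswith("indoor"):
            lux_median[a : min(a + n_door, b)] = lux_median[a - 1]
        if k + 1 < len(cfg.segments) and cfg.segments[k + 1].mode.startswith("indoor") and b < n_total:
            lux_median[max(a, b - n_door) : b] = lux_median[b]
    lux = np.rint(np.exp(rng.normal(np.log(lux_median), cfg.lux_lognormal_sigma)))
    acc = pd.DataFrame({"t": grid, "axis1": ax1, "axis2": ax2, "axis3": ax3, "lux": lux.astype(float)})

    diary = pd.DataFrame(
        {
            "start": [grid[bounds[k]] for k in range(len(cfg.segments))],
            "mode": [TRUTH[s.mode] for s in cfg.segments],
        }
    )
    truth = pd.Series([TRUTH[m] for m in modes], index=range(n_total), dtype="object")
    return SimResult(gps=gps, acc=acc, diary=diary, truth=truth, grid=grid)
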