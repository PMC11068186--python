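"""Rule cascade assigning each epoch an indoor / outdoor / vehicle label.

The cascade works at two levels.  Cluster level: four duration/speed
filters (F1–F4) and an optional building-footprint overlay (F5) mark
clusters indoor, under the premise that nobody dwells inside a 30-metre
circle outdoors for tens of minutes; two corrections then demote indoor
clusters that are betrayed by their light sensor (mean lux above an
indoor-plausible ceiling) or by sitting in a park.  Epoch level: a
vehicle detector aggregates speeds into one-minute windows, flags fast
minutes as driving, and bridges short slow interruptions (traffic lights)
that are flanked by solid driving bouts.

Label precedence is indoor > vehicle > outdoor: an epoch dense enough to
sit in an indoor cluster cannot be mid-drive, and everything neither
indoor nor driving defaults to outdoor.  Each labelled epoch records the
rule that fired (F1…F5, LUX, PARK, DRIVE, DRIVE-BRIDGE, DEFAULT-OUT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .destinations import Area, Cluster
from .geodata import PolygonLayer
from .preprocess import haversine_m

__all__ = [
    "RuleConfig",
    "detect_drive_minutes",
    "bridge_drive_bouts",
    "apply_duration_filters",
    "footprint_filter",
    "corrections",
    "classify_track",
]

INDOOR, OUTDOOR, VEHICLE = "indoor", "outdoor", "vehicle"


@dataclass
class RuleConfig:
    """Thresholds of the classification cascade.

    Duration filters (minutes): F1 marks clusters dwelling at least
    ``f1_min``; F2 needs instance time strictly over ``f2_instance_min``
    at a destination totalling strictly over ``f2_area_min``; F3 needs the
    cluster centre within ``f3_dist_m`` metres of its destination centre
    and at least ``f3_min`` minutes; F4 needs at least ``f4_min`` minutes
    at mean speed strictly below ``f4_speed_mps`` (a slow reference
    walking pace).  ``lux_threshold`` is the mean-lux ceiling (strictly
    over ⇒ reclassified outdoor) and ``frac_inside`` the strict fraction
    of points required inside a polygon for F5/PARK.  Vehicle detection:
    minutes averaging strictly over ``drive_speed_mps`` (25 km/h) are
    driving; non-driving gaps strictly shorter than ``bridge_gap_min``
    flanked by driving bouts, at least one strictly longer than
    ``bridge_bout_min``, are bridged.
    """

    f1_min: float = 30.0
    f2_instance_min: float = 15.0
    f2_area_min: float = 30.0
    f3_dist_m: float = 10.0
    f3_min: float = 15.0
    f4_min: float = 15.0
    f4_speed_mps: float = 0.9
    lux_threshold: float = 240.0
    frac_inside: float = 0.5
    drive_speed_mps: float = 6.944
    drive_window_s: float = 60.0
    bridge_gap_min: float = 3.0
    bridge_bout_min: float = 2.0
    use_footprint_filter: bool = True
    use_lux_correction: bool = True
    use_park_correction: bool = True

    def __post_init__(self) -> None:
        numeric = [
            self.f1_min, self.f2_instance_min, self.f2_area_min, self.f3_dist_m,
            self.f3_min, self.f4_min, self.f4_speed_mps, self.lux_threshold,
            self.drive_speed_mps, self.drive_window_s, self.bridge_gap_min,
            self.bridge_bout_min,
        ]
        if min(numeric) <= 0:
            raise ValueError("all RuleConfig thresholds must be positive")
        if not 0 < self.frac_inside < 1:
            raise ValueError("frac_inside must lie in (0, 1)")


# ---------------------------------------------------------------------------
# vehicle detection


def detect_drive_minutes(track: pd.DataFrame, cfg: RuleConfig | None = None) -> np.ndarray:
    """Flag epochs belonging to fast one-minute windows as driving.

    The track is partitioned into consecutive ``drive_window_s`` windows
    aligned to its first epoch; when the mean of a window's non-missing
    speeds strictly exceeds ``drive_speed_mps`` every epoch in the window
    is flagged.
    """
    cfg = cfg or RuleConfig()
    t = track["t"].astype("int64").to_numpy() / 1e9
    window = np.floor((t - t[0]) / cfg.drive_window_s).astype(int)
    speed = track["speed_mps"].to_numpy(dtype=float)
    flags = np.zeros(len(track), dtype=bool)
    for w in np.unique(window):
        members = window == w
        vals = speed[members]
        vals = vals[~np.isnan(vals)]
        if len(vals) and vals.mean() > cfg.drive_speed_mps:
            flags[members] = True
    return flags


def _runs(flags: np.ndarray):
    """Maximal runs of equal value as (start, stop_exclusive, value)."""
    edges = np.flatnonzero(np.diff(flags.astype(int))) + 1
    bounds = np.concatenate([[0], edges, [len(flags)]])
    return [(int(a), int(b), bool(flags[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def bridge_drive_bouts(flags: np.ndarray, cfg: RuleConfig | None = None, epoch_s: float = 5.0) -> np.ndarray:
    """Absorb short slow interruptions into the surrounding driving trip.

    A maximal non-driving run strictly shorter than ``bridge_gap_min``
    whose immediate neighbours are both driving runs, at least one of them
    strictly longer than ``bridge_bout_min``, is relabelled driving.  The
    rule is applied repeatedly until a fixed point, so bouts grown by a
    bridge can support further bridges.  Returns a new flag array; bridged
    epochs are reported separately by :func:`classify_track` provenance.
    """
    cfg = cfg or RuleConfig()
    out = flags.copy()
    while True:
        runs = _runs(out)
        changed = False
        for k, (a, b, driving) in enumerate(runs):
            if driving or k == 0 or k == len(runs) - 1:
                continue
            gap_min = (b - a) * epoch_s / 60.0
            if gap_min >= cfg.bridge_gap_min:
                continue
            la, lb, _ = runs[k - 1]
            ra, rb, _ = runs[k + 1]
            left_min = (lb - la) * epoch_s / 60.0
            right_min = (rb - ra) * epoch_s / 60.0
            if left_min > cfg.bridge_bout_min or right_min > cfg.bridge_bout_min:
                out[a:b] = True
                changed = True
        if not changed:
            return out


# ---------------------------------------------------------------------------
# cluster filters


def apply_duration_filters(cluster: Cluster, area: Area, cfg: RuleConfig | None = None) -> str | None:
    """Return the first duration/speed filter marking the cluster indoor.

    F1: instance time ≥ f1_min.  F2: instance time > f2_instance_min and
    destination area time > f2_area_min.  F3: cluster centre within
    f3_dist_m of the destination centre and instance time ≥ f3_min.
    F4: instance time ≥ f4_min and mean speed < f4_speed_mps.
    Returns "F1"…"F4" or None.
    """
    cfg = cfg or RuleConfig()
    it = cluster.instance_time_min
    if it >= cfg.f1_min:
        return "F1"
    if it > cfg.f2_instance_min and area.area_time_min > cfg.f2_area_min:
        return "F2"
    d = float(haversine_m(cluster.mean_lat, cluster.mean_lon, area.mean_lat, area.mean_lon))
    if d <= cfg.f3_dist_m and it >= cfg.f3_min:
        return "F3"
    if it >= cfg.f4_min and not np.isnan(cluster.mean_speed_mps) and cluster.mean_speed_mps < cfg.f4_speed_mps:
        return "F4"
    return None


def _frac_points_inside(track: pd.DataFrame, cluster: Cluster, layer: PolygonLayer) -> float:
    prepared = [prep(p) for p in layer.polygons]
    sub = track.iloc[cluster.member_index]
    pts = [Point(lon, lat) for lat, lon in zip(sub["lat"], sub["lon"]) if not np.isnan(lat)]
    if not pts:
        return 0.0
    inside = sum(1 for pt in pts if any(pp.intersects(pt) for pp in prepared))
    return inside / len(pts)


def _center_inside(cluster: Cluster, layer: PolygonLayer) -> bool:
    center = Point(cluster.mean_lon, cluster.mean_lat)
    return any(p.intersects(center) for p in layer.polygons)  # boundary counts as inside


def footprint_filter(track: pd.DataFrame, cluster: Cluster, buildings: PolygonLayer, cfg: RuleConfig | None = None) -> bool:
    """F5: indoor when the mean centre and strictly more than half of the
    cluster's points fall within a building footprint."""
    cfg = cfg or RuleConfig()
    if not _center_inside(cluster, buildings):
        return False
    return _frac_points_inside(track, cluster, buildings) > cfg.frac_inside


def corrections(
    track: pd.DataFrame,
    indoor: dict[int, str],
    clusters: list[Cluster],
    parks: PolygonLayer | None,
    cfg: RuleConfig | None = None,
) -> dict[int, str]:
    """Demote misclassified indoor clusters: lux check first, then park.

    An indoor cluster whose mean lux strictly exceeds ``lux_threshold``
    becomes outdoor (rule LUX); clusters with missing lux skip the check.
    A still-indoor cluster whose centre and strict majority of points sit
    in a park becomes outdoor (rule PARK).  Returns an updated
    cid → rule map where LUX/PARK entries denote outdoor clusters.
    """
    cfg = cfg or RuleConfig()
    out = dict(indoor)
    by_cid = {c.cid: c for c in clusters}
    if cfg.use_lux_correction:
        for cid, rule in list(out.items()):
            if rule in ("LUX", "PARK"):
                continue
            c = by_cid[cid]
            if not np.isnan(c.mean_lux) and c.mean_lux > cfg.lux_threshold:
                out[cid] = "LUX"
    if cfg.use_park_correction and parks is not None and len(parks):
        for cid, rule in list(out.items()):
            if rule in ("LUX", "PARK"):
                continue
            c = by_cid[cid]
            if _center_inside(c, parks) and _frac_points_inside(track, c, parks) > cfg.frac_inside:
                out[cid] = "PARK"
    return out


# ---------------------------------------------------------------------------
# orchestration


def classify_track(
    track: pd.DataFrame,
    clusters: list[Cluster],
    areas: list[Area],
    buildings: PolygonLayer | None = None,
    parks: PolygonLayer | None = None,
    cfg: RuleConfig | None = None,
    epoch_s: float = 5.0,
):
    """Produce the final per-epoch label and rule provenance.

    Cluster-level indoor decisions (F1–F5 then LUX/PARK corrections) are
    broadcast to member epochs; everything else defaults to outdoor; the
    vehicle detector then overrides outdoor epochs — never indoor ones —
    inside fast minutes or bridged gaps.  Returns ``(labeled, info)``
    where ``labeled`` is the track plus ``label``/``rule``/``cid``/``aid``
    columns and ``info`` counts clusters per filter.
    """
    cfg = cfg or RuleConfig()
    area_by_aid = {a.aid: a for a in areas}

    indoor: dict[int, str] = {}
    for c in clusters:
        rule = apply_duration_filters(c, area_by_aid[c.aid], cfg)
        if rule is None and cfg.use_footprint_filter and buildings is not None and len(buildings):
            if footprint_filter(track, c, buildings, cfg):
                rule = "F5"
        if rule is not None:
            indoor[c.cid] = rule
    decisions = corrections(track, indoor, clusters, parks, cfg)

    n = len(track)
    label = np.array([OUTDOOR] * n, dtype=object)
    rule = np.array(["DEFAULT-OUT"] * n, dtype=object)
    cid_col = np.full(n, -1, dtype=int)
    aid_col = np.full(n, -1, dtype=int)
    for c in clusters:
        cid_col[c.member_index] = c.cid
        aid_col[c.member_index] = c.aid
        verdict = decisions.get(c.cid)
        if verdict is None:
            continue
        if verdict in ("LUX", "PARK"):
            label[c.member_index] = OUTDOOR
            rule[c.member_index] = verdict
        else:
            label[c.member_index] = INDOOR
            rule[c.member_index] = verdict

    raw_drive = detect_drive_minutes(track, cfg)
    drive = bridge_drive_bouts(raw_drive, cfg, epoch_s=epoch_s)
    overridable = label == OUTDOOR
    take = drive & overridable
    label[take] = VEHICLE
    rule[take & raw_drive] = "DRIVE"
    rule[take & ~raw_drive] = "DRIVE-BRIDGE"

    labeled = track.copy()
    labeled["label"] = label
    labeled["rule"] = rule
    labeled["cid"] = cid_col
    labeled["aid"] = aid_col
    labeled["imputed"] = (labeled.get("source", "observed") == "imputed")

    info = {
        "clusters_total": len(clusters),
        "indoor_clusters": sum(1 for r in decisions.values() if r not in ("LUX", "PARK")),
        "per_rule": {r: list(decisions.values()).count(r) for r in sorted(set(decisions.values()))},
        "drive_epochs": int(take.sum()),
        "footprint_filter_used": bool(cfg.use_footprint_filter and buildings is not None and len(buildings)),
        "park_correction_used": bool(cfg.use_park_correction and parks is not None and len(parks)),
    }
    return labeled, info
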