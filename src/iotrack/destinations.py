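"""Destination detection: spatio-temporal clustering of GPS epochs.

A *cluster* (CID) is one contiguous visit detected by ST-DBSCAN — DBSCAN
whose neighbourhood requires points to be close in space (within
``eps_space_m`` metres) *and* in time (within ``eps_time_s`` seconds).
With the defaults (30 m, 12 points, 5 min) a cluster is at least one
minute of 5-second fixes dwelling inside a 30-metre-radius area.

Clusters whose spatial mean centres fall within ``area_merge_m`` of each
other are merged (single-linkage) into a *destination* / *area* (AID), so
repeated visits to the same place share an AID.  Each cluster carries
``InstanceTime`` — minutes spent during that visit — and each area carries
``AreaTime`` — cumulative minutes over all of its clusters.

All distances use a local equirectangular projection around the track's
mean latitude; at the ≤30 m scales involved this is indistinguishable from
great-circle distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClusterParams", "Cluster", "Area", "st_dbscan", "cluster_stats", "build_areas", "detect_destinations", "cluster_table"]

_M_PER_DEG_LAT = 111_194.92664455873  # pi/180 * 6,371,000


@dataclass
class ClusterParams:
    """ST-DBSCAN and area-merge parameters.

    eps_space_m : spatial neighbourhood radius (default 30 m)
    min_pts     : minimum points, the point itself included (default 12,
                  i.e. one minute of 5-s epochs)
    eps_time_s  : temporal neighbourhood half-width (default 300 s)
    area_merge_m: cluster mean centres closer than this share an area
                  (default 30 m)
    """

    eps_space_m: float = 30.0
    min_pts: int = 12
    eps_time_s: float = 300.0
    area_merge_m: float = 30.0

    def __post_init__(self) -> None:
        if min(self.eps_space_m, self.min_pts, self.eps_time_s, self.area_merge_m) <= 0:
            raise ValueError("all ClusterParams fields must be positive")


@dataclass
class Cluster:
    cid: int
    member_index: np.ndarray  # positional indices into the track
    aid: int = -1
    mean_lat: float = float("nan")
    mean_lon: float = float("nan")
    t_start: pd.Timestamp = None
    t_end: pd.Timestamp = None
    instance_time_min: float = float("nan")
    mean_speed_mps: float = float("nan")
    mean_lux: float = float("nan")


@dataclass
class Area:
    aid: int
    cluster_ids: list[int] = field(default_factory=list)
    mean_lat: float = float("nan")
    mean_lon: float = float("nan")
    area_time_min: float = float("nan")


def local_xy(lat, lon, lat0: float, lon0: float):
    """Project WGS84 degrees to metres in a local equirectangular frame."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    x = (lon - lon0) * _M_PER_DEG_LAT * np.cos(np.radians(lat0))
    y = (lat - lat0) * _M_PER_DEG_LAT
    return x, y


def _neighbourhoods(x, y, t, p: ClusterParams):
    """Boolean neighbourhood matrix: within eps_space AND within eps_time."""
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    close = dx * dx + dy * dy <= p.eps_space_m**2
    near = np.abs(t[:, None] - t[None, :]) <= p.eps_time_s
    return close & near


def st_dbscan(track: pd.DataFrame, p: ClusterParams | None = None) -> np.ndarray:
    """Label each epoch with a cluster id (−1 for unclustered).

    A point is a *core* point when at least ``min_pts`` points (itself
    included) lie within ``eps_space_m`` metres and ``eps_time_s`` seconds
    of it.  Clusters grow by standard DBSCAN expansion over this
    space–time neighbourhood, scanning points in time order; border points
    join the first cluster that reaches them.  Epochs without a usable
    position are never clustered.
    """
    p = p or ClusterParams()
    n = len(track)
    labels = np.full(n, -1, dtype=int)
    usable = (track["lat"].notna() & ~track.get("noise", pd.Series(False, index=track.index)).fillna(False).astype(bool)).to_numpy()
    pos = np.flatnonzero(usable)
    if len(pos) == 0:
        return labels

    lat = track["lat"].to_numpy(dtype=float)[pos]
    lon = track["lon"].to_numpy(dtype=float)[pos]
    t = (track["t"].astype("int64").to_numpy() / 1e9)[pos]
    x, y = local_xy(lat, lon, float(np.mean(lat)), float(np.mean(lon)))

    nbr = _neighbourhoods(x, y, t, p)
    counts = nbr.sum(axis=1)
    core = counts >= p.min_pts

    m = len(pos)
    sub_labels = np.full(m, -1, dtype=int)
    visited = np.zeros(m, dtype=bool)
    cid = 0
    for i in range(m):
        if visited[i] or not core[i]:
            continue
        # breadth-first expansion of a new cluster from core point i
        sub_labels[i] = cid
        visited[i] = True
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k in np.flatnonzero(nbr[j]):
                if sub_labels[k] == -1:
                    sub_labels[k] = cid
                    if core[k] and not visited[k]:
                        visited[k] = True
                        frontier.append(k)
        cid += 1
    labels[pos] = sub_labels
    return labels


def cluster_stats(track: pd.DataFrame, labels: np.ndarray, epoch_s: float = 5.0) -> list[Cluster]:
    """Compute per-cluster summaries used by the classification filters.

    ``instance_time_min`` counts the closed span of the visit — last tick
    minus first tick plus one epoch — so twelve 5-s epochs give exactly
    1.0 minute.  Mean centre is the arithmetic mean of member lat/lon
    (adequate at ≤30 m extents); mean speed and mean lux average the
    members' non-missing values.
    """
    clusters: list[Cluster] = []
    for cid in sorted(set(labels[labels >= 0])):
        members = np.flatnonzero(labels == cid)
        sub = track.iloc[members]
        t0, t1 = sub["t"].iloc[0], sub["t"].iloc[-1]
        speeds = sub["speed_mps"].dropna() if "speed_mps" in sub else pd.Series(dtype=float)
        lux = sub["lux"].dropna() if "lux" in sub else pd.Series(dtype=float)
        clusters.append(
            Cluster(
                cid=int(cid),
                member_index=members,
                mean_lat=float(sub["lat"].mean()),
                mean_lon=float(sub["lon"].mean()),
                t_start=t0,
                t_end=t1,
                instance_time_min=((t1 - t0).total_seconds() + epoch_s) / 60.0,
                mean_speed_mps=float(speeds.mean()) if len(speeds) else float("nan"),
                mean_lux=float(lux.mean()) if len(lux) else float("nan"),
            )
        )
    return clusters


def build_areas(clusters: list[Cluster], p: ClusterParams | None = None) -> list[Area]:
    """Merge clusters into areas (destinations) by mean-centre proximity.

    Single-linkage: clusters whose mean centres are within
    ``area_merge_m`` of each other (transitively) share one area.  Mutates
    each cluster's ``aid`` and returns the areas.
    """
    p = p or ClusterParams()
    if not clusters:
        return []
    lat = np.array([c.mean_lat for c in clusters])
    lon = np.array([c.mean_lon for c in clusters])
    x, y = local_xy(lat, lon, float(lat.mean()), float(lon.mean()))

    parent = list(range(len(clusters)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if (x[i] - x[j]) ** 2 + (y[i] - y[j]) ** 2 <= p.area_merge_m**2:
                parent[find(i)] = find(j)

    roots: dict[int, int] = {}
    areas: list[Area] = []
    for i, c in enumerate(clusters):
        r = find(i)
        if r not in roots:
            roots[r] = len(areas)
            areas.append(Area(aid=len(areas)))
        aid = roots[r]
        c.aid = aid
        areas[aid].cluster_ids.append(c.cid)
    for area in areas:
        members = [c for c in clusters if c.aid == area.aid]
        area.mean_lat = float(np.mean([c.mean_lat for c in members]))
        area.mean_lon = float(np.mean([c.mean_lon for c in members]))
        area.area_time_min = float(sum(c.instance_time_min for c in members))
    return areas


def detect_destinations(track: pd.DataFrame, p: ClusterParams | None = None, epoch_s: float = 5.0):
    """Full destination detection: cluster, summarise, merge into areas.

    Returns ``(labels, clusters, areas)``.
    """
    p = p or ClusterParams()
    labels = st_dbscan(track, p)
    clusters = cluster_stats(track, labels, epoch_s=epoch_s)
    areas = build_areas(clusters, p)
    return labels, clusters, areas


def cluster_table(clusters: list[Cluster], areas: list[Area]) -> pd.DataFrame:
    """Cluster summary table mirroring the four destination variables."""
    area_time = {a.aid: a.area_time_min for a in areas}
    return pd.DataFrame(
        {
            "AID": [c.aid for c in clusters],
            "CID": [c.cid for c in clusters],
            "InstanceTime": [c.instance_time_min for c in clusters],
            "AreaTime": [area_time.get(c.aid, float("nan")) for c in clusters],
            "mean_lat": [c.mean_lat for c in clusters],
            "mean_lon": [c.mean_lon for c in clusters],
            "mean_speed_mps": [c.mean_speed_mps for c in clusters],
            "mean_lux": [c.mean_lux for c in clusters],
        }
    )
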