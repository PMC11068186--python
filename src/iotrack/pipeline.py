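"""End-to-end orchestration: link → preprocess → cluster → classify → validate.

`run_pipeline` is the programmatic core of the command-line ``run``
subcommand.  It is deterministic: identical inputs and configuration
produce byte-identical outputs (all randomness lives in the synthetic
generator's seeds), and it writes a manifest recording the configuration
and the bookkeeping counts (noise-flagged, imputed, clusters per filter)
so a run can be audited later.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import geodata
from .classify import RuleConfig, classify_track
from .destinations import ClusterParams, cluster_table, detect_destinations
from .preprocess import PreprocessConfig, preprocess_track
from .validate import align_diary, confusion, two_class_view

log = logging.getLogger("iotrack")

__all__ = ["RunConfig", "run_pipeline", "load_run_config", "evaluate_synthetic_session"]


def evaluate_synthetic_session(
    seed: int,
    segments=None,
    low_noise: bool = True,
    rules: RuleConfig | None = None,
    epoch_s: float = 5.0,
):
    """Simulate one ground-truthed session and score the classifier on it.

    Generates a synthetic world and track for ``seed``, runs the full
    chain (link, preprocess, cluster, classify) with the given rule
    configuration, and compares the labels against the session's diary.
    Returns ``(three_class, two_class, labeled, truth)`` where the first
    two are :class:`~iotrack.validate.ConfusionSummary` objects.
    """
    from . import synthgen  # local import: simulation is optional for pipeline users

    world = synthgen.make_world(seed)
    if low_noise:
        cfg = synthgen.low_noise_config(seed, segments)
    else:
        cfg = synthgen.ScenarioConfig(seed=seed, segments=segments or synthgen.default_segments())
    sim = synthgen.simulate_track(world, cfg)
    track = geodata.link_streams(sim.gps, sim.acc, epoch_s=epoch_s)
    track, _ = preprocess_track(track, PreprocessConfig(epoch_s=epoch_s))
    _, clusters, areas = detect_destinations(track, ClusterParams(), epoch_s=epoch_s)
    labeled, _ = classify_track(track, clusters, areas, world.buildings, world.parks, rules or RuleConfig(), epoch_s=epoch_s)
    truth = align_diary(sim.diary, labeled)
    three = confusion(truth, labeled["label"])
    two = two_class_view(truth, labeled["label"])
    return three, two, labeled, truth


@dataclass
class RunConfig:
    gps_path: str
    acc_path: str
    out_dir: str
    buildings_path: str | None = None
    parks_path: str | None = None
    diary_path: str | None = None
    gps_format: str = "csv"  # or "gpx"
    epoch_s: float = 5.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    rules: RuleConfig = field(default_factory=RuleConfig)


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a TOML file with [preprocess]/[cluster]/[rules] tables."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kw = {k: v for k, v in raw.items() if k not in ("preprocess", "cluster", "rules")}
    return RunConfig(
        **kw,
        preprocess=PreprocessConfig(**raw.get("preprocess", {})),
        cluster=ClusterParams(**raw.get("cluster", {})),
        rules=RuleConfig(**raw.get("rules", {})),
    )


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _metrics_dict(summary) -> dict:
    return {
        "matrix": {t: {p: int(summary.matrix.loc[t, p]) for p in summary.matrix.columns} for t in summary.matrix.index},
        "overall_accuracy": summary.overall_acc,
        "users_accuracy": summary.users_acc,
        "producers_accuracy": summary.producers_acc,
        "kappa": summary.kappa,
        "n": summary.n,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full classification chain and write all artifacts.

    Writes ``labeled.csv``, ``clusters.csv``, ``manifest.json`` and — when
    a diary is supplied — ``metrics.json`` under ``cfg.out_dir``.  Returns
    the manifest dictionary.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    reader = geodata.read_gpx if cfg.gps_format == "gpx" else geodata.read_gps_csv
    fixes = reader(cfg.gps_path)
    epochs = geodata.read_epoch_csv(cfg.acc_path)
    buildings = geodata.read_polygon_layer(cfg.buildings_path, "building") if cfg.buildings_path else None
    parks = geodata.read_polygon_layer(cfg.parks_path, "park") if cfg.parks_path else None

    track = geodata.link_streams(fixes, epochs, epoch_s=cfg.epoch_s)
    track, pp_stats = preprocess_track(track, cfg.preprocess)
    log.info("preprocess: %(noise_flagged)d noise-flagged, %(imputed)d imputed", pp_stats)

    labels, clusters, areas = detect_destinations(track, cfg.cluster, epoch_s=cfg.epoch_s)
    log.info("destinations: %d clusters in %d areas", len(clusters), len(areas))

    labeled, info = classify_track(track, clusters, areas, buildings, parks, cfg.rules, epoch_s=cfg.epoch_s)
    geodata.write_labeled(labeled, out_dir / "labeled.csv")
    cluster_table(clusters, areas).to_csv(out_dir / "clusters.csv", index=False)

    manifest = {
        "config_hash": _config_hash(cfg),
        "config": dataclasses.asdict(cfg),
        "n_epochs": len(labeled),
        "preprocess": pp_stats,
        "classify": info,
        "skipped": [s for s, used in (("F5", info["footprint_filter_used"]), ("PARK", info["park_correction_used"])) if not used],
    }

    if cfg.diary_path:
        diary = geodata.read_diary_csv(cfg.diary_path)
        truth = align_diary(diary, labeled)
        three = confusion(truth, labeled["label"])
        two = two_class_view(truth, labeled["label"])
        metrics = {"three_class": _metrics_dict(three), "two_class": _metrics_dict(two)}
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        manifest["metrics"] = {
            "three_class_overall": three.overall_acc,
            "two_class_overall": two.overall_acc,
            "two_class_kappa": two.kappa,
        }

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
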