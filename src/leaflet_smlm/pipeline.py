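"""Configuration-driven end-to-end pipeline.

Chains simulate -> subsample -> cluster -> DoC -> track -> TALL from a single
structured (YAML) configuration with one global seed. Per-stage seeds are
derived deterministically from the global seed and the stage name, so a
stage re-run standalone with its derived seed reproduces its pipeline
output bit-for-bit. Every run writes a manifest listing the configuration
hash, the derived seeds and a checksum for each output file.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import doc as _doc
from . import tall as _tall
from . import tracking as _tracking
from .io import TrajectorySet, subsample, write_localizations, write_trajectories
from .roi import ROI
from .simulate import (
    SceneConfig,
    TrajectoryModelParams,
    gen_paired_channels,
    gen_trajectories,
)

ALL_STAGES = ("simulate", "cluster", "doc", "track", "tall")


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


def default_config() -> dict:
    """Default configuration mirroring the acquisition conditions:
    4 ms/frame for 2000 frames, 9.36-um analysis crop, R_max/dR = 500/50 nm,
    50-nm detection circle with a 32-ms trapped-period threshold."""
    return {
        "seed": 0,
        "output_dir": "pipeline_out",
        "stages": {s: True for s in ALL_STAGES},
        "roi": {"x_min": 0.0, "y_min": 0.0, "x_max": 9360.0, "y_max": 9360.0},
        "scene_a": {
            "n_clusters": 20,
            "cluster_radius_sd": 45.0,
            "locs_per_cluster": 50,
            "background_locs": 5000,
            "localization_precision_sd": 22.0,
            "mean_blink_repeats": 1.5,
        },
        "scene_b": {
            "n_clusters": 20,
            "cluster_radius_sd": 45.0,
            "locs_per_cluster": 50,
            "background_locs": 5000,
            "localization_precision_sd": 26.3,
            "mean_blink_repeats": 1.5,
        },
        "coloc_fraction": 0.8,
        "subsample_n": 15000,
        "doc": {"r_max": 500.0, "dr": 50.0},
        "trajectory": {
            "model": "brownian",
            "D": 1.0,
            "frame_interval": 0.004,
            "n_frames": 50,
            "localization_precision_sd": 22.2,
        },
        "n_trajectories": 200,
        "windows": ["12ms@4ms", "24ms@4ms"],
        "tall": {"detection_radius": 50.0, "threshold_trapped_period": 0.032},
        "cluster": {"n_simulations": 20},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with a stage-name hash."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _config_hash(cfg: dict) -> str:
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(cfg: dict) -> dict:
    """Fill defaults, check stage dependencies; raises before any stage runs."""
    merged = default_config()
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key] = {**merged[key], **val}
        else:
            merged[key] = val
    stages = merged["stages"]
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    for dep in ("cluster", "doc"):
        if stages.get(dep) and not stages.get("simulate"):
            raise ConfigError(f"stage {dep!r} requires stage 'simulate'")
    for dep in ("track", "tall"):
        if stages.get(dep) and not stages.get("simulate"):
            raise ConfigError(f"stage {dep!r} requires stage 'simulate'")
    # construct parameter objects now so bad blocks fail before running
    ROI(**merged["roi"])
    SceneConfig(**merged["scene_a"])
    SceneConfig(**merged["scene_b"])
    _doc.DoCParams(**merged["doc"])
    TrajectoryModelParams(**merged["trajectory"])
    _tall.TALLParams(**merged["tall"])
    for w in merged["windows"]:
        if w not in _tracking.FIT_WINDOWS:
            raise ConfigError(f"unknown fit window {w!r}")
    return merged


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run the enabled stages in dependency order; returns the manifest."""
    cfg = validate_config(config)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    seed = int(cfg["seed"])
    roi = ROI(**cfg["roi"])
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "global_seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in ALL_STAGES if stages.get(s)},
        "outputs": {},
        "report": {},
    }

    def _emit(stage: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].setdefault(stage, {})[name] = _file_checksum(path)

    table_a = table_b = None
    trajectories: TrajectorySet | None = None

    if stages.get("simulate"):
        s = stage_seed(seed, "simulate")
        cfg_a = SceneConfig(**cfg["scene_a"], seed=s)
        cfg_b = SceneConfig(**cfg["scene_b"], seed=s + 1)
        table_a, table_b, _truth = gen_paired_channels(
            cfg_a, cfg_b, cfg["coloc_fraction"], roi, seed=s
        )
        n_sub = cfg.get("subsample_n")
        if n_sub:
            table_a = subsample(table_a, n_sub, seed=s + 2)
            table_b = subsample(table_b, n_sub, seed=s + 3)
        params_t = TrajectoryModelParams(**cfg["trajectory"], seed=s + 4)
        trajectories = gen_trajectories(params_t, cfg["n_trajectories"], roi)
        _emit("simulate", "channel_a.csv", lambda p: write_localizations(table_a, p))
        _emit("simulate", "channel_b.csv", lambda p: write_localizations(table_b, p))
        _emit(
            "simulate",
            "trajectories.csv",
            lambda p: write_trajectories(trajectories, p),
        )

    if stages.get("cluster"):
        s = stage_seed(seed, "cluster")
        vmap = _cluster.voronoi_densities(table_a, roi)
        thr = _cluster.csr_threshold(
            table_a, roi, n_simulations=cfg["cluster"]["n_simulations"], seed=s
        )
        segmented = _cluster.segment_clusters(vmap, thr)
        summary = _cluster.cluster_summary(segmented)
        _emit(
            "cluster",
            "clusters.csv",
            lambda p: segmented.table.to_csv(p, index=False),
        )
        labeled = table_a.copy()
        labeled["cluster_id"] = segmented.labels
        _emit(
            "cluster",
            "localizations_labeled.csv",
            lambda p: labeled.to_csv(p, index=False),
        )
        manifest["report"]["cluster"] = {
            "threshold_nm2": float(thr),
            "clusters_detectable": thr.clusters_detectable,
            **{k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in summary.items()},
        }

    if stages.get("doc"):
        s = stage_seed(seed, "doc")
        params_d = _doc.DoCParams(**cfg["doc"])
        result = _doc.doc_scores(table_a, table_b, params_d)
        control = _doc.doc_control(table_a, table_b, params_d, seed=s, roi=roi)
        index = _doc.coloc_index(result)
        index_ctrl = _doc.coloc_index(control)
        _emit(
            "doc",
            "doc_scores_a.csv",
            lambda p: result.channel_a.to_csv(p, index=False),
        )
        _emit(
            "doc",
            "doc_scores_b.csv",
            lambda p: result.channel_b.to_csv(p, index=False),
        )
        hist = pd.DataFrame(
            {
                "bin_left": result.hist_bin_edges[:-1],
                "bin_right": result.hist_bin_edges[1:],
                "count_a": result.histogram("a"),
                "count_b": result.histogram("b"),
            }
        )
        _emit("doc", "doc_histogram.csv", lambda p: hist.to_csv(p, index=False))
        manifest["report"]["doc"] = {
            "index": index["pooled"]["index"],
            "index_control": index_ctrl["pooled"]["index"],
            "control_seed": s,
        }

    if stages.get("track"):
        curve = _tracking.ensemble_msd(trajectories)
        ens = pd.DataFrame(
            {
                "lag_s": curve.lags,
                "msd_um2": curve.msd,
                "se_um2": curve.se,
                "n_segments": curve.n_segments,
            }
        )
        _emit("track", "ensemble_msd.csv", lambda p: ens.to_csv(p, index=False))
        fits = {}
        for w in cfg["windows"]:
            try:
                fits[w] = asdict(_tracking.fit_deff(curve, w))
            except ValueError:
                fits[w] = None  # window extends past the curve
        per = _tracking.per_trajectory_deff(trajectories, cfg["windows"][0])
        _emit(
            "track",
            "deff_per_trajectory.csv",
            lambda p: per.to_csv(p, index=False),
        )
        manifest["report"]["track"] = {"ensemble_fits": fits}

    if stages.get("tall"):
        params_l = _tall.TALLParams(**cfg["tall"])
        results = _tall.analyze_set(trajectories, params_l)
        summary = _tall.tall_summary(results)
        rows = [
            {
                "trajectory": i,
                "start": e.start,
                "end": e.end,
                "duration_s": e.n_frames * r.frame_interval,
                "radius_of_gyration_nm": e.radius_of_gyration,
            }
            for i, r in enumerate(results)
            if r.analyzed and not r.immobile
            for e in r.events
        ]
        events = pd.DataFrame(
            rows, columns=["trajectory", "start", "end", "duration_s", "radius_of_gyration_nm"]
        )
        _emit("tall", "tall_events.csv", lambda p: events.to_csv(p, index=False))
        d = asdict(summary)
        d["tau_tall"] = None if np.isnan(summary.tau_tall) else summary.tau_tall
        manifest["report"]["tall"] = d

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
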