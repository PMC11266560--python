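"""Synthetic localization patterns and single-molecule trajectories.

The generators reproduce the statistical structure the downstream analyses
assume so that every stage can be verified against ground truth:

* homogeneous Poisson ("complete spatial randomness", CSR) point patterns —
  the null model for cluster thresholding and the Rand-Rand colocalization
  control;
* clustered scenes: isotropic Gaussian domains (~150-250 nm across) over a
  CSR background, with multi-blink overcounting (each true emission is
  re-localized 1 + Poisson(mean-1) times with fresh localization error);
* coupled two-channel scenes with a tunable fraction of shared domain
  centers;
* trajectories: simple Brownian diffusion, confinement in a circular zone,
  hop diffusion between ~58-nm grid compartments, and immobile probes —
  sampled at a fixed frame interval and perturbed by localization error.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrajectorySet
from .roi import ROI

# measured single-molecule localization precisions (nm) of the two probes
# used for dual-color imaging, and of the tracking probe
PRECISION_MEOS4B_NM = 26.3
PRECISION_SF650B_NM = 22.0
PRECISION_TDSTAYGOLD_NM = 22.2

DEFAULT_FRAME_RANGE = (1, 2000)  # 4 ms/frame for 2000 frames

NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one clustered-channel scene."""

    n_clusters: int = 20
    cluster_radius_sd: float = 45.0  # nm, Gaussian spread of member points
    locs_per_cluster: int = 50
    background_locs: int = 5000
    localization_precision_sd: float = PRECISION_SF650B_NM
    mean_blink_repeats: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.locs_per_cluster, self.background_locs) < 0:
            raise ValueError("counts must be >= 0")
        if self.cluster_radius_sd < 0 or self.localization_precision_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.mean_blink_repeats < 1:
            raise ValueError("mean_blink_repeats must be >= 1")


@dataclass(frozen=True)
class TrajectoryModelParams:
    """Parameters of one trajectory model."""

    model: str = "brownian"  # brownian | confined | hop | immobile
    D: float = 1.0  # um^2/s
    frame_interval: float = 0.004  # s
    n_frames: int = 50
    confinement_radius: float = 100.0  # nm
    compartment_size: float = 58.0  # nm, picket-fence compartment side
    hop_probability: float = 0.1  # per boundary encounter
    localization_precision_sd: float = 0.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("brownian", "confined", "hop", "immobile"):
            raise ValueError(f"unknown trajectory model: {self.model!r}")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.compartment_size <= 0 or self.confinement_radius <= 0:
            raise ValueError("length scales must be > 0")
        if not 0 <= self.hop_probability <= 1:
            raise ValueError("hop_probability must be in [0, 1]")


def _table(x, y, frames, **extra) -> pd.DataFrame:
    cols = {"frame": np.asarray(frames, dtype=int), "x": x, "y": y}
    cols.update(extra)
    return pd.DataFrame(cols)


def gen_csr(
    n: int,
    roi: ROI | None = None,
    seed: int = 0,
    frame_range: tuple[int, int] = DEFAULT_FRAME_RANGE,
) -> pd.DataFrame:
    """Homogeneous Poisson pattern: ``n`` i.i.d. uniform points in the ROI."""
    if n < 0:
        raise ValueError("n must be >= 0")
    roi = roi or ROI.default()
    rng = np.random.default_rng(seed)
    x = rng.uniform(roi.x_min, roi.x_max, size=n)
    y = rng.uniform(roi.y_min, roi.y_max, size=n)
    frames = rng.integers(frame_range[0], frame_range[1] + 1, size=n)
    return _table(x, y, frames)


def _emit_clustered(
    config: SceneConfig, roi: ROI, rng: np.random.Generator, centers: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray]:
    """Emit member + background localizations given cluster centers."""
    true_xy = []
    labels = []
    for ci, c in enumerate(centers):
        need = config.locs_per_cluster
        got = []
        attempts = 0
        while len(got) < need and attempts < 1000:
            pts = c + rng.normal(0.0, config.cluster_radius_sd, size=(4 * need, 2))
            inside = roi.contains(pts[:, 0], pts[:, 1])
            if attempts == 0 and inside.mean() < 0.01:
                warnings.warn(
                    "cluster spread so large that <1% of members fall in the "
                    "ROI; members generated by rejection",
                    stacklevel=3,
                )
            got.extend(pts[inside][: need - len(got)])
            attempts += 1
        true_xy.append(np.asarray(got))
        labels.append(np.full(len(got), ci))
    n_bg = config.background_locs
    bg = np.column_stack(
        [
            rng.uniform(roi.x_min, roi.x_max, size=n_bg),
            rng.uniform(roi.y_min, roi.y_max, size=n_bg),
        ]
    )
    true_xy.append(bg)
    labels.append(np.full(n_bg, -1))
    xy = np.concatenate([a.reshape(-1, 2) for a in true_xy]) if true_xy else np.empty((0, 2))
    lab = np.concatenate(labels) if labels else np.empty(0, dtype=int)

    # multi-blink overcounting: 1 + Poisson(mean - 1) appearances per emitter
    repeats = 1 + rng.poisson(config.mean_blink_repeats - 1.0, size=len(xy))
    xy = np.repeat(xy, repeats, axis=0)
    lab = np.repeat(lab, repeats)
    xy = xy + rng.normal(0.0, config.localization_precision_sd, size=xy.shape)
    # localizations pushed out of the field by localization error are cropped
    # away, as they would be in an image crop; the count is reported
    inside = roi.contains(xy[:, 0], xy[:, 1])
    n_rejected = int((~inside).sum())
    xy, lab = xy[inside], lab[inside]
    frames = rng.integers(DEFAULT_FRAME_RANGE[0], DEFAULT_FRAME_RANGE[1] + 1, size=len(xy))
    table = _table(xy[:, 0], xy[:, 1], frames)
    return table, lab.astype(int), n_rejected


def gen_clustered_scene(
    config: SceneConfig, roi: ROI | None = None
) -> tuple[pd.DataFrame, dict]:
    """Clustered scene with ground truth.

    Returns ``(table, truth)`` where ``truth`` has ``centers`` (n_clusters, 2)
    and ``labels`` — per localization, the cluster index or -1 for background.
    """
    roi = roi or ROI.default()
    rng = np.random.default_rng(config.seed)
    centers = np.column_stack(
        [
            rng.uniform(roi.x_min, roi.x_max, size=config.n_clusters),
            rng.uniform(roi.y_min, roi.y_max, size=config.n_clusters),
        ]
    )
    table, labels, n_rejected = _emit_clustered(config, roi, rng, centers)
    return table, {"centers": centers, "labels": labels, "n_rejected": n_rejected}


def gen_paired_channels(
    config_a: SceneConfig,
    config_b: SceneConfig,
    coloc_fraction: float,
    roi: ROI | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two coupled clustered channels.

    A fraction ``coloc_fraction`` of channel-B cluster centers coincides with
    (randomly chosen) channel-A centers; the remainder are independent.
    Returns ``(table_a, table_b, truth)``.
    """
    if not 0 <= coloc_fraction <= 1:
        raise ValueError("coloc_fraction must be in [0, 1]")
    roi = roi or ROI.default()
    rng = np.random.default_rng(seed)
    centers_a = np.column_stack(
        [
            rng.uniform(roi.x_min, roi.x_max, size=config_a.n_clusters),
            rng.uniform(roi.y_min, roi.y_max, size=config_a.n_clusters),
        ]
    )
    n_shared = int(round(coloc_fraction * config_b.n_clusters))
    n_shared = min(n_shared, config_a.n_clusters)
    shared_idx = rng.choice(config_a.n_clusters, size=n_shared, replace=False) if n_shared else np.empty(0, int)
    free = np.column_stack(
        [
            rng.uniform(roi.x_min, roi.x_max, size=config_b.n_clusters - n_shared),
            rng.uniform(roi.y_min, roi.y_max, size=config_b.n_clusters - n_shared),
        ]
    )
    centers_b = np.concatenate([centers_a[shared_idx], free]) if config_b.n_clusters else free
    table_a, labels_a, rej_a = _emit_clustered(config_a, roi, rng, centers_a)
    table_b, labels_b, rej_b = _emit_clustered(config_b, roi, rng, centers_b)
    truth = {
        "centers_a": centers_a,
        "centers_b": centers_b,
        "labels_a": labels_a,
        "labels_b": labels_b,
        "n_shared": n_shared,
        "n_rejected": (rej_a, rej_b),
    }
    return table_a, table_b, truth


def random_shift(
    table: pd.DataFrame, max_shift: float = 1000.0, seed: int = 0, roi: ROI | None = None
) -> pd.DataFrame:
    """Pseudo-localization control: shift every point by a random vector.

    Each localization is translated by an angle uniform on [0, 2pi) and a
    distance uniform on [0, max_shift]; coordinates are wrapped toroidally
    into the ROI so the count and mean density are preserved.
    """
    if max_shift <= 0:
        raise ValueError("max_shift must be > 0")
    roi = roi or ROI.default()
    out = table.copy()
    if len(table) == 0:
        return out
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2 * np.pi, size=len(table))
    dist = rng.uniform(0.0, max_shift, size=len(table))
    x = out["x"].to_numpy(float) + dist * np.cos(theta)
    y = out["y"].to_numpy(float) + dist * np.sin(theta)
    out["x"] = roi.x_min + np.mod(x - roi.x_min, roi.width)
    out["y"] = roi.y_min + np.mod(y - roi.y_min, roi.height)
    return out


# ---------------------------------------------------------------------------
# trajectories


def _steps_nm(rng, n, d_um2_s, dt) -> np.ndarray:
    sd = np.sqrt(2.0 * d_um2_s * NM2_PER_UM2 * dt)  # nm, per axis
    return rng.normal(0.0, sd, size=(n, 2))


def _reflect_into_circle(p: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point back inside a circle (clamped for huge steps)."""
    v = p - center
    d = float(np.hypot(*v))
    if d <= radius:
        return p
    # clamp guards steps larger than the zone diameter
    d_new = float(np.clip(2 * radius - d, 0.0, radius))
    return center + v * (d_new / d)


def _hop_walk(rng, n_steps, start, steps, size, p_hop) -> np.ndarray:
    """Brownian walk on a square compartment grid with semi-permeable walls.

    Each axis is treated independently: a proposed move that crosses a grid
    line is accepted with probability ``p_hop`` per encounter, otherwise
    reflected off the wall.
    """
    pos = np.empty((n_steps + 1, 2))
    pos[0] = start
    cur = start.astype(float).copy()
    for i in range(n_steps):
        for ax in (0, 1):
            comp = np.floor(cur[ax] / size)
            lo, hi = comp * size, (comp + 1) * size
            p = cur[ax] + steps[i, ax]
            # resolve successive wall encounters (steps ~ compartment size)
            for _ in range(64):
                if p > hi:
                    if rng.uniform() < p_hop:
                        comp += 1
                        lo, hi = comp * size, (comp + 1) * size
                    else:
                        p = 2 * hi - p
                elif p < lo:
                    if rng.uniform() < p_hop:
                        comp -= 1
                        lo, hi = comp * size, (comp + 1) * size
                    else:
                        p = 2 * lo - p
                else:
                    break
            else:
                p = np.clip(p, lo, hi)
            cur[ax] = p
        pos[i + 1] = cur
    return pos


def gen_trajectories(
    params: TrajectoryModelParams, n_trajectories: int, roi: ROI | None = None
) -> TrajectorySet:
    """Simulate a set of 2-D trajectories of one motion model.

    Brownian steps have per-axis variance 2*D*dt; the confined model reflects
    the walk at a circular boundary around its start; the hop model walks on
    a square compartment grid with per-encounter transmission probability;
    immobile probes are static. Localization error is added to every
    position afterwards.
    """
    if n_trajectories < 0:
        raise ValueError("n_trajectories must be >= 0")
    roi = roi or ROI.default()
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    n_steps = params.n_frames - 1
    records = []
    for t in range(n_trajectories):
        start = np.array(
            [rng.uniform(roi.x_min, roi.x_max), rng.uniform(roi.y_min, roi.y_max)]
        )
        if params.model == "immobile":
            pos = np.tile(start, (params.n_frames, 1))
        elif params.model == "brownian":
            steps = _steps_nm(rng, n_steps, params.D, dt)
            pos = start + np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        elif params.model == "confined":
            steps = _steps_nm(rng, n_steps, params.D, dt)
            pos = np.empty((params.n_frames, 2))
            pos[0] = start
            for i in range(n_steps):
                pos[i + 1] = _reflect_into_circle(
                    pos[i] + steps[i], start, params.confinement_radius
                )
        else:  # hop
            steps = _steps_nm(rng, n_steps, params.D, dt)
            pos = _hop_walk(
                rng, n_steps, start, steps, params.compartment_size, params.hop_probability
            )
        if params.localization_precision_sd > 0:
            pos = pos + rng.normal(0.0, params.localization_precision_sd, size=pos.shape)
        records.append(
            pd.DataFrame(
                {
                    "track_id": np.full(params.n_frames, t),
                    "frame": np.arange(1, params.n_frames + 1),
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                }
            )
        )
    data = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["track_id", "frame", "x", "y"])
    )
    return TrajectorySet(data=data, frame_interval=dt, meta={"model": params.model, "D": params.D})
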