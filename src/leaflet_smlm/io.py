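"""Localization-table and trajectory I/O, post-processing filters, and the
normalized spot-count statistic.

Localization tables are plain :class:`pandas.DataFrame` objects with the
canonical columns ``frame`` (int, 1-based), ``x``/``y`` (float, nm) and the
optional columns ``uncertainty`` (nm) and ``intensity`` (photons). Two CSV
dialects are supported: the ThunderSTORM convention with unit-annotated
headers (``"x [nm]"``) and a bare-header convention (``x``).

Trajectories are stored as one table per set (``track_id, frame, x, y``)
together with a single frame interval; tracks with frame gaps are split at
the gaps rather than interpolated, since interpolation would fabricate the
displacements used downstream by the MSD and confinement analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class FormatError(ValueError):
    """A file violates the expected tabular format."""


MANDATORY_COLUMNS = ("frame", "x", "y")

# ThunderSTORM-style header -> canonical name
_TS_HEADER = {
    "frame": "frame",
    "x [nm]": "x",
    "y [nm]": "y",
    "uncertainty [nm]": "uncertainty",
    "uncertainty_xy [nm]": "uncertainty",
    "intensity [photon]": "intensity",
}
_TS_REVERSE = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "uncertainty": "uncertainty [nm]",
    "intensity": "intensity [photon]",
}


def _canonical_name(header: str) -> str:
    h = header.strip().strip('"')
    if h in _TS_HEADER:
        return _TS_HEADER[h]
    # strip any bracketed unit annotation on unknown columns
    return re.sub(r"\s*\[.*\]$", "", h) if h.endswith("]") else h


def validate_localizations(table: pd.DataFrame) -> pd.DataFrame:
    """Check the localization-table invariants; returns the table."""
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    for col in MANDATORY_COLUMNS:
        vals = table[col].to_numpy()
        bad = ~np.isfinite(vals.astype(float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(f"non-finite value in column {col!r} at row {row}")
    return table


def read_localizations(path, dialect: str = "auto") -> pd.DataFrame:
    """Read a localization CSV in ThunderSTORM or bare-header dialect.

    Unknown columns are preserved unchanged. Raises :class:`FormatError`
    when a mandatory column is missing or a coordinate is non-numeric
    (the message carries the offending 1-based data line).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [_canonical_name(c) for c in raw.columns]
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"{path.name}: missing mandatory column: {col!r}")
    out = {}
    for col in raw.columns:
        if col in ("x", "y", "uncertainty", "intensity"):
            vals = pd.to_numeric(raw[col], errors="coerce")
            if col in ("x", "y") and vals.isna().any():
                line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
                raise FormatError(f"{path.name}: non-numeric {col!r} at line {line}")
            out[col] = vals.astype(float)
        elif col == "frame":
            vals = pd.to_numeric(raw[col], errors="coerce")
            if vals.isna().any():
                line = int(vals.isna().idxmax()) + 2
                raise FormatError(f"{path.name}: non-numeric 'frame' at line {line}")
            out[col] = vals.astype(int)
        else:
            out[col] = raw[col]
    table = pd.DataFrame(out)
    return validate_localizations(table)


def write_localizations(table: pd.DataFrame, path, dialect: str = "thunderstorm") -> None:
    """Write a localization table as CSV (round-trips through the reader)."""
    validate_localizations(table)
    df = table.copy()
    if dialect == "thunderstorm":
        df.columns = [_TS_REVERSE.get(c, c) for c in df.columns]
    elif dialect != "bare":
        raise ValueError(f"unknown dialect: {dialect!r}")
    df.to_csv(path, index=False, float_format="%.4f")


def remove_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Merge same-frame localizations closer than their uncertainty.

    Within each frame, whenever two localizations lie closer than the larger
    of their two uncertainties, only the higher-intensity member is kept
    (ties keep the earlier record). Idempotent; mirrors a detection-software
    "remove duplicates, distance threshold = uncertainty" post-processing
    step used to suppress double-fitted emitters.
    """
    validate_localizations(table)
    if "uncertainty" not in table.columns or table["uncertainty"].isna().any():
        raise ValueError("remove_duplicates requires an 'uncertainty' for every record")

    intensity = (
        table["intensity"].to_numpy(float)
        if "intensity" in table.columns
        else np.zeros(len(table))
    )
    keep_mask = np.ones(len(table), dtype=bool)
    for _, idx in table.groupby("frame").indices.items():
        if len(idx) < 2:
            continue
        pts = table.iloc[idx][["x", "y"]].to_numpy(float)
        unc = table.iloc[idx]["uncertainty"].to_numpy(float)
        inten = intensity[idx]
        # precedence: intensity desc, then original order
        order = np.lexsort((np.arange(len(idx)), -inten))
        kept: list[int] = []
        tree = cKDTree(pts)
        r_all = float(unc.max())
        for local in order:
            ok = True
            if kept:
                for other in tree.query_ball_point(pts[local], r_all):
                    if other == local or other not in kept:
                        continue
                    thr = max(unc[local], unc[other])
                    if np.hypot(*(pts[local] - pts[other])) < thr:
                        ok = False
                        break
            if ok:
                kept.append(local)
        drop = set(range(len(idx))) - set(kept)
        for local in drop:
            keep_mask[idx[local]] = False
    return table.loc[keep_mask].reset_index(drop=True)


def subsample(table: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Draw exactly ``min(n, len(table))`` records uniformly without replacement.

    Used to equalize localization density across images (e.g. 15,000
    localizations per image). Deterministic given ``seed``; output is sorted
    by frame then original order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= len(table):
        return table.sort_values("frame", kind="stable").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n, replace=False)
    out = table.iloc[np.sort(idx)]
    return out.sort_values("frame", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SpotCountStats:
    """Inputs of the expression-normalized spot-count statistic."""

    n_spots_expressing: int
    n_spots_control: int
    intensity_cytoplasm: float
    intensity_background: float

    def __post_init__(self) -> None:
        if self.n_spots_expressing < 0 or self.n_spots_control < 0:
            raise ValueError("spot counts must be >= 0")


def normalized_spot_density(stats: SpotCountStats) -> float:
    """Background-subtracted spot count normalized by expression level.

    (spots in expressing cells - spots in non-expressing control) divided by
    (cytoplasmic fluorescence - background fluorescence). The denominator
    must be positive.
    """
    denom = stats.intensity_cytoplasm - stats.intensity_background
    if denom <= 0:
        raise ValueError(
            "intensity_cytoplasm must exceed intensity_background "
            f"(got {stats.intensity_cytoplasm} <= {stats.intensity_background})"
        )
    return (stats.n_spots_expressing - stats.n_spots_control) / denom


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectorySet:
    """A set of 2-D single-molecule trajectories sharing one frame interval.

    ``data`` holds columns ``track_id, frame, x, y`` (frames strictly
    increasing and consecutive within a track; every track has >= 2 points).
    ``frame_interval`` is in seconds. Coordinates in nm.
    """

    data: pd.DataFrame
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        req = {"track_id", "frame", "x", "y"}
        if not req <= set(self.data.columns):
            raise FormatError(f"trajectory table needs columns {sorted(req)}")

    @property
    def n_trajectories(self) -> int:
        return self.data["track_id"].nunique()

    def __len__(self) -> int:
        return self.n_trajectories

    def iter_tracks(self) -> Iterator[tuple[object, np.ndarray]]:
        """Yield ``(track_id, positions)``; positions shaped (N, 2) in nm."""
        for tid, grp in self.data.groupby("track_id", sort=False):
            yield tid, grp[["x", "y"]].to_numpy(float)


def split_track_gaps(set_: TrajectorySet) -> TrajectorySet:
    """Split tracks at frame gaps; drop fragments shorter than 2 points.

    A gap is any frame increment larger than 1. New fragment ids are
    ``"<track_id>/<k>"`` when a track splits.
    """
    pieces = []
    for tid, grp in set_.data.groupby("track_id", sort=False):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise FormatError(f"track {tid!r}: frames not strictly increasing")
        breaks = np.flatnonzero(np.diff(frames) > 1) + 1
        segments = np.split(np.arange(len(frames)), breaks)
        multi = len(segments) > 1
        for k, seg in enumerate(segments):
            if len(seg) < 2:
                continue
            sub = grp.iloc[seg].copy()
            if multi:
                sub["track_id"] = f"{tid}/{k}"
            pieces.append(sub)
    data = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else set_.data.iloc[0:0].copy()
    )
    return TrajectorySet(data=data, frame_interval=set_.frame_interval, meta=dict(set_.meta))


_INTERVAL_RE = re.compile(r"#\s*frame_interval_s\s*=\s*([0-9.eE+-]+)")


def write_trajectories(set_: TrajectorySet, path) -> None:
    """Write a trajectory set as CSV with the frame interval in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_s = {set_.frame_interval!r}\n")
        set_.data[["track_id", "frame", "x", "y"]].to_csv(fh, index=False)


def read_trajectories(path, frame_interval: float | None = None) -> TrajectorySet:
    """Read a trajectory CSV; tracks with frame gaps are split at the gaps.

    The frame interval is taken from a leading ``# frame_interval_s = ...``
    comment unless given explicitly. Non-monotone frames within a track are
    a format error; single-point fragments are rejected (dropped).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        m = _INTERVAL_RE.match(first)
        if m:
            file_dt = float(m.group(1))
            data = pd.read_csv(fh)
        else:
            file_dt = None
            fh.seek(0)
            data = pd.read_csv(fh)
    dt = frame_interval if frame_interval is not None else file_dt
    if dt is None:
        raise FormatError(f"{path.name}: no frame interval declared")
    req = {"track_id", "frame", "x", "y"}
    missing = req - set(data.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    data["frame"] = data["frame"].astype(int)
    data[["x", "y"]] = data[["x", "y"]].astype(float)
    return split_track_gaps(TrajectorySet(data=data, frame_interval=dt))
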