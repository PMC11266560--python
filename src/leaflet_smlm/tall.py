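"""Detection of Temporary Arrest of LateraL diffusion (TALL) events.

A TALL candidate is a maximal run of consecutive trajectory positions that
all stay within a detection circle (default radius 50 nm) around the run's
own centroid; the centroid is recomputed as the run grows and the expansion
is greedy from every start, with longest-run-wins selection (ties broken by
the earlier start). Candidates shorter than the threshold trapped period
(32 ms at 4-ms resolution, 8 ms at 1-ms resolution) are discarded, and
retained events separated by fewer than 2 frames are merged.

A trajectory whose single merged event spans >= 90% of its duration and
whose overall radius of gyration does not exceed the immobile reference
bound is classified immobile; the bound defaults to sqrt(2) times the
22.2-nm localization precision of a fluorescent probe fixed on glass — the
expected 2-D radius of gyration of a truly stationary emitter seen through
localization error.

Set-level summaries pool per-frame state (mobile / TALL / immobile) over all
analyzed trajectories; tau_TALL is the mean duration of merged TALL events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import TrajectorySet

FIXED_PROBE_PRECISION_NM = 22.2


@dataclass(frozen=True)
class TALLParams:
    """Detection parameters for confinement events."""

    detection_radius: float = 50.0  # nm
    threshold_trapped_period: float = 0.032  # s (use 0.008 at 1-ms resolution)
    min_trajectory_length: int = 10  # frames; longer-than rule
    immobile_reference_sd: float = np.sqrt(2.0) * FIXED_PROBE_PRECISION_NM  # nm
    merge_gap_frames: int = 2  # events separated by < this many frames merge

    def __post_init__(self) -> None:
        if self.detection_radius <= 0:
            raise ValueError("detection_radius must be > 0")
        if self.min_trajectory_length < 3:
            raise ValueError("min_trajectory_length must be >= 3")

    def validate_for_interval(self, frame_interval: float) -> None:
        if self.threshold_trapped_period < 2 * frame_interval:
            raise ValueError(
                "threshold_trapped_period must be >= 2 frame intervals "
                f"({self.threshold_trapped_period} s < {2 * frame_interval} s)"
            )


@dataclass
class TALLEvent:
    start: int  # frame index into the trajectory (0-based, inclusive)
    end: int  # inclusive
    centroid: tuple[float, float]
    radius_of_gyration: float  # nm

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


@dataclass
class TALLResult:
    """Per-trajectory confinement events and state classification."""

    events: list[TALLEvent]
    n_frames: int
    frame_interval: float
    immobile: bool
    analyzed: bool
    skip_reason: str = ""

    @property
    def tall_frames(self) -> int:
        if self.immobile:
            return 0
        return sum(e.n_frames for e in self.events)

    def durations(self) -> np.ndarray:
        """Event durations in seconds (n_frames * dt)."""
        return np.array([e.n_frames * self.frame_interval for e in self.events])


def _radius_of_gyration(pos: np.ndarray) -> float:
    c = pos.mean(axis=0)
    return float(np.sqrt(((pos - c) ** 2).sum(axis=1).mean()))


def _max_run_from(pos: np.ndarray, start: int, radius: float) -> int:
    """Inclusive end of the longest centroid-circle run beginning at start."""
    csum = np.zeros(2)
    end = start
    csum += pos[start]
    for j in range(start + 1, len(pos)):
        csum += pos[j]
        centroid = csum / (j - start + 1)
        seg = pos[start : j + 1]
        if np.max(((seg - centroid) ** 2).sum(axis=1)) > radius**2:
            break
        end = j
    return end


def detect_tall(
    pos: np.ndarray, frame_interval: float, params: TALLParams | None = None
) -> TALLResult:
    """Detect TALL events in one trajectory ((N, 2) positions in nm).

    Trajectories not longer than ``min_trajectory_length`` frames are skipped
    (``analyzed=False``) rather than raising.
    """
    params = params or TALLParams()
    params.validate_for_interval(frame_interval)
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    if n <= params.min_trajectory_length:
        return TALLResult(
            events=[],
            n_frames=n,
            frame_interval=frame_interval,
            immobile=False,
            analyzed=False,
            skip_reason=f"trajectory length {n} <= {params.min_trajectory_length}",
        )

    min_frames = int(np.ceil(params.threshold_trapped_period / frame_interval - 1e-9))
    # maximal runs: greedy expansion from each start; longest-run-wins with
    # earlier starts taking precedence, then merge near-contiguous events
    events: list[tuple[int, int]] = []
    i = 0
    while i < n:
        end = _max_run_from(pos, i, params.detection_radius)
        if end - i + 1 >= min_frames:
            events.append((i, end))
            i = end + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for s, e in events:
        if merged and s - merged[-1][1] < params.merge_gap_frames:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out = [
        TALLEvent(
            start=s,
            end=e,
            centroid=tuple(pos[s : e + 1].mean(axis=0)),
            radius_of_gyration=_radius_of_gyration(pos[s : e + 1]),
        )
        for s, e in merged
    ]
    immobile = (
        len(out) == 1
        and out[0].n_frames >= 0.9 * n
        and _radius_of_gyration(pos) <= params.immobile_reference_sd
    )
    return TALLResult(
        events=out,
        n_frames=n,
        frame_interval=frame_interval,
        immobile=immobile,
        analyzed=True,
    )


@dataclass
class TALLSummary:
    """Pooled mobile/TALL/immobile time fractions and mean TALL lifetime."""

    fraction_mobile: float
    fraction_tall: float
    fraction_immobile: float
    tau_tall: float  # s; NaN when no TALL event was observed
    n_trajectories: int
    n_frames: int
    n_events: int

    def fractions(self) -> np.ndarray:
        return np.array(
            [self.fraction_mobile, self.fraction_tall, self.fraction_immobile]
        )


def analyze_set(
    trajectories: TrajectorySet, params: TALLParams | None = None
) -> list[TALLResult]:
    """Run :func:`detect_tall` over every trajectory of a set."""
    params = params or TALLParams()
    return [
        detect_tall(pos, trajectories.frame_interval, params)
        for _, pos in trajectories.iter_tracks()
    ]


def tall_summary(results: list[TALLResult]) -> TALLSummary:
    """Pool per-frame state over all analyzed trajectories.

    Frames of immobile trajectories count as immobile in full; frames inside
    TALL events of mobile trajectories count as TALL; the rest are mobile.
    tau_TALL is the mean merged-event duration (immobile trajectories'
    events excluded).
    """
    analyzed = [r for r in results if r.analyzed]
    if not analyzed:
        raise ValueError("no analyzed trajectory (all skipped?)")
    total = sum(r.n_frames for r in analyzed)
    immobile = sum(r.n_frames for r in analyzed if r.immobile)
    tall = sum(r.tall_frames for r in analyzed if not r.immobile)
    durations = np.concatenate(
        [r.durations() for r in analyzed if not r.immobile]
        or [np.empty(0)]
    )
    return TALLSummary(
        fraction_mobile=(total - immobile - tall) / total,
        fraction_tall=tall / total,
        fraction_immobile=immobile / total,
        tau_tall=float(durations.mean()) if len(durations) else float("nan"),
        n_trajectories=len(analyzed),
        n_frames=total,
        n_events=int(len(durations)),
    )
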