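"""Degree-of-colocalization (DoC) analysis for dual-channel localization maps.

For every localization Ai of channel A, the number of channel-A and
channel-B localizations inside closed disks of increasing radius r is
counted. The counts are area-corrected and normalized by the count at the
largest radius R_max,

    D(r) = [N(r) / N(R_max)] * [R_max^2 / r^2],

so a spatially uniform pattern has expected D(r) = 1 at every r. The two
radial density gradients D_Ai,A and D_Ai,B are compared by a Spearman rank
correlation S over the radius bins, and the per-localization DoC score is

    C_Ai = S_Ai * exp(-E_Ai,B / R_max),

where E_Ai,B is the distance from Ai to its nearest channel-B neighbor; the
exponential factor suppresses rank agreement between patterns that never
come close to each other. C ranges from -1 (segregated) through 0 (no
colocalization) to +1 (totally colocalized). Channel B is scored
symmetrically. Localizations for which both within-R_max counts fall below
``min_total_localizations`` are excluded because their gradients cannot be
estimated accurately.

Counting conventions: the focal localization is not counted in its own
channel, and a cross-channel localization lying at exactly zero distance
from the focal point (the registration image of the same emitter, e.g. when
one channel is a coordinate copy of the other) is likewise not counted in
the gradient; the nearest-neighbor weight E does use all cross-channel
points. These two choices make a uniform pattern give mean D(r) = 1 at
every radius and make an exact channel copy score C = +1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .roi import ROI
from .simulate import random_shift

HIST_BIN_EDGES = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)  # width 0.1
INDEX_BIN = (0.7, 1.0)


@dataclass(frozen=True)
class DoCParams:
    """Radial binning and exclusion parameters of the DoC analysis."""

    r_max: float = 500.0  # nm
    dr: float = 50.0  # nm
    min_total_localizations: int | None = None  # default (r_max/dr) * 10

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.dr <= 0:
            raise ValueError("r_max and dr must be > 0")
        n = self.r_max / self.dr
        if abs(n - round(n)) > 1e-9:
            raise ValueError("r_max must be a positive multiple of dr")
        if self.min_total_localizations is None:
            object.__setattr__(
                self, "min_total_localizations", int(round(n)) * 10
            )

    @property
    def radii(self) -> np.ndarray:
        """Bin radii dR, 2dR, ..., R_max (the r = 0 term is absent)."""
        n = int(round(self.r_max / self.dr))
        return self.dr * np.arange(1, n + 1)


@dataclass
class RadialDensityGradient:
    """Radial density gradients around one focal localization."""

    focal: int
    radii: np.ndarray
    n_own: np.ndarray
    n_other: np.ndarray
    d_own: np.ndarray  # NaN-filled when undefined
    d_other: np.ndarray
    defined: bool


def _counts(focal_pts: np.ndarray, tree: cKDTree, radii: np.ndarray) -> np.ndarray:
    """Closed-disk cumulative counts, shape (n_focal, n_radii)."""
    out = np.empty((len(focal_pts), len(radii)), dtype=np.int64)
    for j, r in enumerate(radii):
        out[:, j] = tree.query_ball_point(focal_pts, float(r), return_length=True)
    return out


def _gradient_counts(
    focal_pts: np.ndarray,
    own_tree: cKDTree,
    other_tree: cKDTree,
    radii: np.ndarray,
    own_is_focal_channel: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts with the focal point removed from its own channel and any
    zero-distance cross-channel point removed from the other channel."""
    n_own = _counts(focal_pts, own_tree, radii)
    if own_is_focal_channel:
        n_own = n_own - 1  # the focal localization itself
    n_other = _counts(focal_pts, other_tree, radii)
    coincident = other_tree.query_ball_point(focal_pts, 0.0, return_length=True)
    n_other = n_other - coincident[:, None]
    return n_own, n_other


def _normalize(n: np.ndarray, radii: np.ndarray, r_max: float) -> np.ndarray:
    """D(r) = N(r)/N(R_max) * R_max^2/r^2; NaN where N(R_max) = 0."""
    total = n[:, -1].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = n / total[:, None] * (r_max**2 / radii**2)
    d[total == 0] = np.nan
    return d


def density_gradients(
    a: pd.DataFrame, b: pd.DataFrame, focal: int, params: DoCParams | None = None
) -> RadialDensityGradient:
    """Radial density gradients of both channels around localization ``a[focal]``."""
    params = params or DoCParams()
    pts_a = a[["x", "y"]].to_numpy(float)
    pts_b = b[["x", "y"]].to_numpy(float)
    if not 0 <= focal < len(pts_a):
        raise IndexError(f"focal index {focal} out of range")
    fp = pts_a[focal : focal + 1]
    n_own, n_other = _gradient_counts(
        fp, cKDTree(pts_a), cKDTree(pts_b), params.radii
    )
    d_own = _normalize(n_own, params.radii, params.r_max)
    d_other = _normalize(n_other, params.radii, params.r_max)
    defined = bool(n_own[0, -1] > 0 and n_other[0, -1] > 0)
    return RadialDensityGradient(
        focal=focal,
        radii=params.radii,
        n_own=n_own[0],
        n_other=n_other[0],
        d_own=d_own[0],
        d_other=d_other[0],
        defined=defined,
    )


def mean_density_gradient(
    table: pd.DataFrame,
    params: DoCParams | None = None,
    n_focals: int | None = None,
    seed: int = 0,
    roi: ROI | None = None,
    edge_margin: float | None = None,
) -> pd.DataFrame:
    """Per-bin mean and standard error of the own-channel D(r) profile.

    Averages D_Ai,A(r) over ``n_focals`` randomly chosen focal localizations
    (all of them when None). The calibration check for the DoC statistic: a
    uniform pattern must give mean D(r) = 1 at every radius. That expectation
    holds exactly only for focal points whose R_max disk lies inside the
    window containing points, so when an ROI is given, focal points closer
    than ``edge_margin`` (default R_max) to its boundary are not used —
    their clipped disks would inflate D at small radii.
    """
    params = params or DoCParams()
    pts = table[["x", "y"]].to_numpy(float)
    eligible = np.arange(len(pts))
    if roi is not None:
        margin = params.r_max if edge_margin is None else edge_margin
        ok = (
            (pts[:, 0] >= roi.x_min + margin)
            & (pts[:, 0] <= roi.x_max - margin)
            & (pts[:, 1] >= roi.y_min + margin)
            & (pts[:, 1] <= roi.y_max - margin)
        )
        eligible = np.flatnonzero(ok)
    if n_focals is not None and n_focals < len(eligible):
        rng = np.random.default_rng(seed)
        idx = rng.choice(eligible, size=n_focals, replace=False)
    else:
        idx = eligible
    tree = cKDTree(pts)
    n_own = _counts(pts[idx], tree, params.radii) - 1
    d = _normalize(n_own, params.radii, params.r_max)
    ok = ~np.isnan(d[:, -1])
    d = d[ok]
    return pd.DataFrame(
        {
            "r_nm": params.radii,
            "mean_D": d.mean(axis=0),
            "se_D": d.std(axis=0, ddof=1) / np.sqrt(len(d)),
            "n_focals": len(d),
        }
    )


# ---------------------------------------------------------------------------
# scoring


@dataclass
class DoCResult:
    """Per-localization DoC scores for both channels.

    Each channel table has columns ``S`` (Spearman coefficient), ``E_nm``
    (nearest cross-channel neighbor distance), ``C`` (DoC score), ``scored``
    and ``exclusion_reason`` (empty string when scored).
    """

    channel_a: pd.DataFrame
    channel_b: pd.DataFrame
    params: DoCParams
    control_seed: int | None = None
    hist_bin_edges: np.ndarray = field(default_factory=lambda: HIST_BIN_EDGES.copy())

    def scores(self, channel: str) -> np.ndarray:
        tbl = self.channel_a if channel == "a" else self.channel_b
        return tbl.loc[tbl["scored"], "C"].to_numpy(float)

    def pooled_scores(self) -> np.ndarray:
        return np.concatenate([self.scores("a"), self.scores("b")])

    def histogram(self, channel: str) -> np.ndarray:
        return np.histogram(self.scores(channel), bins=self.hist_bin_edges)[0]


def _score_channel(
    focal_pts: np.ndarray,
    own_tree: cKDTree,
    other_tree: cKDTree,
    params: DoCParams,
) -> pd.DataFrame:
    n_own, n_other = _gradient_counts(focal_pts, own_tree, other_tree, params.radii)
    d_own = _normalize(n_own, params.radii, params.r_max)
    d_other = _normalize(n_other, params.radii, params.r_max)
    e_dist, _ = other_tree.query(focal_pts, k=1)

    m = len(focal_pts)
    s = np.full(m, np.nan)
    reason = np.full(m, "", dtype=object)

    undefined = (n_own[:, -1] <= 0) | (n_other[:, -1] <= 0)
    reason[undefined] = "undefined gradient"
    low = (
        (n_own[:, -1] < params.min_total_localizations)
        & (n_other[:, -1] < params.min_total_localizations)
        & ~undefined
    )
    reason[low] = "low count"

    cand = ~(undefined | low)
    if cand.any():
        ra = rankdata(d_own[cand], axis=1)
        rb = rankdata(d_other[cand], axis=1)
        ra_c = ra - ra.mean(axis=1, keepdims=True)
        rb_c = rb - rb.mean(axis=1, keepdims=True)
        na2 = (ra_c**2).sum(axis=1)
        nb2 = (rb_c**2).sum(axis=1)
        degen = (na2 == 0) | (nb2 == 0)
        sc = np.full(cand.sum(), np.nan)
        ok = ~degen
        # sqrt of the product (not product of sqrts) so identical rank
        # vectors give S = 1.0 exactly; clip guards rounding overshoot
        sc[ok] = np.clip(
            (ra_c * rb_c).sum(axis=1)[ok] / np.sqrt(na2[ok] * nb2[ok]), -1.0, 1.0
        )
        s[cand] = sc
        cand_idx = np.flatnonzero(cand)
        reason[cand_idx[degen]] = "degenerate gradient"

    scored = reason == ""
    c = np.where(scored, s * np.exp(-e_dist / params.r_max), np.nan)
    return pd.DataFrame(
        {
            "S": s,
            "E_nm": e_dist,
            "C": c,
            "scored": scored,
            "exclusion_reason": reason,
        }
    )


def doc_scores(
    a: pd.DataFrame, b: pd.DataFrame, params: DoCParams | None = None
) -> DoCResult:
    """Score every localization of both channels.

    Raises when either channel is empty (the nearest-neighbor distance would
    be undefined).
    """
    params = params or DoCParams()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both channels must be non-empty")
    pts_a = a[["x", "y"]].to_numpy(float)
    pts_b = b[["x", "y"]].to_numpy(float)
    tree_a = cKDTree(pts_a)
    tree_b = cKDTree(pts_b)
    return DoCResult(
        channel_a=_score_channel(pts_a, tree_a, tree_b, params),
        channel_b=_score_channel(pts_b, tree_b, tree_a, params),
        params=params,
    )


def coloc_index(result: DoCResult) -> dict:
    """Fraction (and raw count) of scored localizations with C in [0.7, 1].

    Reported per channel and pooled. The fraction normalizes the raw
    summation by the number of scored localizations so images with different
    localization counts are comparable; the raw count is kept alongside.
    """
    out = {}
    lo, hi = INDEX_BIN
    pooled_num = 0
    pooled_den = 0
    for ch in ("a", "b"):
        c = result.scores(ch)
        if len(c) == 0:
            out[ch] = {"index": np.nan, "raw_count": 0, "n_scored": 0, "defined": False}
            continue
        num = int(((c >= lo) & (c <= hi)).sum())
        out[ch] = {
            "index": num / len(c),
            "raw_count": num,
            "n_scored": int(len(c)),
            "defined": True,
        }
        pooled_num += num
        pooled_den += len(c)
    out["pooled"] = {
        "index": pooled_num / pooled_den if pooled_den else np.nan,
        "raw_count": pooled_num,
        "n_scored": pooled_den,
        "defined": pooled_den > 0,
    }
    return out


def doc_control(
    a: pd.DataFrame,
    b: pd.DataFrame,
    params: DoCParams | None = None,
    seed: int = 0,
    roi: ROI | None = None,
    max_shift: float = 1000.0,
) -> DoCResult:
    """Randomized control: score channel A against a randomly shifted copy of B.

    Every B localization is translated in a random direction by a random
    distance (toroidal wrap into the ROI), destroying true cross-channel
    correlations while preserving each channel's internal structure.
    """
    shifted = random_shift(b, max_shift=max_shift, seed=seed, roi=roi)
    result = doc_scores(a, shifted, params)
    result.control_seed = seed
    return result
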