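"""Voronoi-tessellation cluster segmentation of localization maps.

Each localization's local density is estimated as the inverse of its Voronoi
cell area (first-rank density). Cells are clipped to the ROI exactly by
tessellating the point set together with its mirror images across the four
ROI edges, which makes every original cell finite and bounded by the ROI, so
the clipped cell areas tile the ROI exactly.

Domains are segmented by thresholding the density at a level determined by
Monte-Carlo comparison against complete spatial randomness (CSR), taking
connected components of above-threshold cells over the shared-edge adjacency
graph, and discarding components with five or fewer localizations. Domain
sizes are reported as circle-equivalent diameters, 2*sqrt(area/pi), with the
median over domains as the headline size statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi
from scipy.spatial._qhull import QhullError

from .roi import ROI
from .simulate import gen_csr

MIN_CLUSTER_LOCALIZATIONS = 6  # components with <= 5 members are eliminated


class DegenerateGeometryError(ValueError):
    """Fewer than 3 points, or all points collinear."""


@dataclass
class VoronoiMap:
    """Per-localization Voronoi cells clipped to an ROI."""

    points: np.ndarray  # (n, 2) nm
    areas: np.ndarray  # (n,) nm^2, clipped cell areas
    densities: np.ndarray  # (n,) nm^-2, 1/area
    adjacency: sparse.csr_matrix  # symmetric shared-edge graph
    roi: ROI
    polygons: list = field(repr=False, default_factory=list)  # (k, 2) vertex arrays

    def __len__(self) -> int:
        return len(self.points)


def _mirror_points(pts: np.ndarray, roi: ROI) -> np.ndarray:
    """Original points followed by their reflections across the 4 ROI edges."""
    left = pts.copy()
    left[:, 0] = 2 * roi.x_min - pts[:, 0]
    right = pts.copy()
    right[:, 0] = 2 * roi.x_max - pts[:, 0]
    bottom = pts.copy()
    bottom[:, 1] = 2 * roi.y_min - pts[:, 1]
    top = pts.copy()
    top[:, 1] = 2 * roi.y_max - pts[:, 1]
    return np.concatenate([pts, left, right, bottom, top])


def voronoi_densities(
    table: pd.DataFrame, roi: ROI | None = None, neighbor_averaged: bool = False
) -> VoronoiMap:
    """Tessellate a localization table and return clipped areas and densities.

    Requires at least 3 non-collinear localizations inside the ROI. Border
    cells are clipped to the ROI (not discarded), so the clipped areas sum
    to the ROI area. The default density estimate is the first-rank (own
    cell) density 1/area; with ``neighbor_averaged=True`` the density of a
    localization is instead (1 + number of adjacent cells) divided by the
    summed area of its cell and the adjacent cells, a less noisy estimate
    that improves the member/background separation of tight domains.
    """
    roi = roi or ROI.default()
    pts = table[["x", "y"]].to_numpy(float)
    inside = roi.contains(pts[:, 0], pts[:, 1])
    if not inside.all():
        raise ValueError("all localizations must lie inside the ROI")
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 localizations")
    # collinear input has no 2-D tessellation of its own; the mirror trick
    # would silently "repair" it, so detect and refuse explicitly
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise DegenerateGeometryError("all localizations are collinear")
    try:
        vor = Voronoi(_mirror_points(pts, roi))
    except QhullError as exc:  # collinear or otherwise degenerate input
        raise DegenerateGeometryError(str(exc)) from exc

    areas = np.empty(n)
    polygons = []
    verts = vor.vertices
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise DegenerateGeometryError(
                f"unbounded cell for localization {i}; point on ROI boundary?"
            )
        v = verts[region]
        polygons.append(v)
        x, y = v[:, 0], v[:, 1]
        # shoelace formula
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if (areas <= 0).any():
        raise DegenerateGeometryError("zero-area Voronoi cell (coincident points?)")

    rp = vor.ridge_points
    mask = (rp[:, 0] < n) & (rp[:, 1] < n)
    ij = rp[mask]
    data = np.ones(len(ij), dtype=bool)
    adj = sparse.coo_matrix(
        (np.concatenate([data, data]), (np.concatenate([ij[:, 0], ij[:, 1]]),
                                        np.concatenate([ij[:, 1], ij[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    if neighbor_averaged:
        n_neigh = np.asarray(adj.sum(axis=1)).ravel()
        densities = (1.0 + n_neigh) / (areas + adj @ areas)
    else:
        densities = 1.0 / areas
    return VoronoiMap(
        points=pts,
        areas=areas,
        densities=densities,
        adjacency=adj,
        roi=roi,
        polygons=polygons,
    )


@dataclass
class ThresholdResult:
    """Density threshold from the Monte-Carlo CSR comparison."""

    threshold: float  # nm^-2; +inf when no clustering is detectable
    clusters_detectable: bool
    bin_edges: np.ndarray
    observed_hist: np.ndarray
    csr_hist_mean: np.ndarray

    def __float__(self) -> float:
        return float(self.threshold)


def csr_threshold(
    table: pd.DataFrame,
    roi: ROI | None = None,
    n_simulations: int = 100,
    seed: int = 0,
    n_bins: int = 50,
    neighbor_averaged: bool = False,
) -> ThresholdResult:
    """Monte-Carlo density threshold separating clusters from CSR noise.

    The density histogram of the observed map is compared with the mean
    histogram of ``n_simulations`` CSR maps of identical point count and ROI
    (50 shared bins, range capped at the pooled 99.9th percentile so a single
    extreme cell cannot compress the binning). The threshold is the lower
    edge of the first bin above the CSR mode where the observed histogram
    meets or exceeds the CSR mean *and* the observed tail mass beyond that
    edge exceeds the CSR tail mass by more than three simulation standard
    deviations — the latter guards against declaring a threshold from
    histogram noise on unclustered input. If no such bin exists the result
    carries ``threshold = +inf`` and ``clusters_detectable = False``.
    """
    roi = roi or ROI.default()
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    obs = voronoi_densities(table, roi, neighbor_averaged).densities
    n = len(obs)
    rng = np.random.default_rng(seed)
    sim_dens = []
    for _ in range(n_simulations):
        sub = gen_csr(n, roi, seed=int(rng.integers(2**31)))
        sim_dens.append(voronoi_densities(sub, roi, neighbor_averaged).densities)
    pooled = np.concatenate([obs, *sim_dens])
    upper = float(np.percentile(pooled, 99.9))
    edges = np.linspace(0.0, upper, n_bins + 1)

    obs_hist, _ = np.histogram(obs, bins=edges)
    sim_hists = np.stack([np.histogram(d, bins=edges)[0] for d in sim_dens])
    csr_mean = sim_hists.mean(axis=0)
    mode_bin = int(np.argmax(csr_mean))

    for b in range(mode_bin + 1, n_bins):
        if obs_hist[b] < csr_mean[b]:
            continue
        edge = edges[b]
        tail_obs = int((obs >= edge).sum())
        tails = np.array([(d >= edge).sum() for d in sim_dens], dtype=float)
        if tail_obs > tails.mean() + 3.0 * max(tails.std(), 1.0):
            return ThresholdResult(float(edge), True, edges, obs_hist, csr_mean)
    return ThresholdResult(np.inf, False, edges, obs_hist, csr_mean)


@dataclass
class ClusterSet:
    """Segmented domains: member indices, areas and equivalent diameters."""

    table: pd.DataFrame  # cluster_id, n_localizations, area_nm2, diameter_nm
    members: list  # list of index arrays into the VoronoiMap
    labels: np.ndarray  # per localization: cluster_id or -1
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.table)


def segment_clusters(
    vmap: VoronoiMap,
    threshold: float | ThresholdResult,
    min_localizations: int = MIN_CLUSTER_LOCALIZATIONS,
) -> ClusterSet:
    """Connected components of above-threshold cells; small components dropped.

    A localization belongs to a cluster when its density is >= threshold and
    it is edge-connected to the other members. Components with fewer than
    ``min_localizations`` members (default: five or fewer) are eliminated.
    Cluster area is the union (= sum, cells are disjoint) of member cell areas.
    """
    thr = float(threshold)
    if not thr > 0:
        raise ValueError("threshold must be > 0")
    n = len(vmap)
    above = vmap.densities >= thr
    labels = np.full(n, -1, dtype=int)
    rows = []
    members: list[np.ndarray] = []
    if above.any() and np.isfinite(thr):
        sub_idx = np.flatnonzero(above)
        sub_adj = vmap.adjacency[sub_idx][:, sub_idx]
        n_comp, comp = connected_components(sub_adj, directed=False)
        next_id = 0
        for c in range(n_comp):
            mem = sub_idx[comp == c]
            if len(mem) < min_localizations:
                continue
            area = float(vmap.areas[mem].sum())
            rows.append(
                {
                    "cluster_id": next_id,
                    "n_localizations": len(mem),
                    "area_nm2": area,
                    "diameter_nm": 2.0 * np.sqrt(area / np.pi),
                }
            )
            labels[mem] = next_id
            members.append(mem)
            next_id += 1
    table = pd.DataFrame(
        rows, columns=["cluster_id", "n_localizations", "area_nm2", "diameter_nm"]
    )
    return ClusterSet(table=table, members=members, labels=labels, threshold=thr)


def cluster_summary(clusters: ClusterSet) -> dict:
    """Count and size statistics of a segmented domain set.

    The median equivalent diameter (lower interpolation for even counts) is
    the headline domain-size statistic; domains are treated as circles.
    """
    d = clusters.table["diameter_nm"].to_numpy(float)
    if len(d) == 0:
        return {
            "n_clusters": 0,
            "median_diameter_nm": np.nan,
            "q1_diameter_nm": np.nan,
            "q3_diameter_nm": np.nan,
            "total_area_nm2": 0.0,
            "defined": False,
        }
    return {
        "n_clusters": int(len(d)),
        "median_diameter_nm": float(np.percentile(d, 50, method="lower")),
        "q1_diameter_nm": float(np.percentile(d, 25, method="lower")),
        "q3_diameter_nm": float(np.percentile(d, 75, method="lower")),
        "total_area_nm2": float(clusters.table["area_nm2"].sum()),
        "defined": True,
    }
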