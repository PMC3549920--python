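"""Voxel-level functional networks and their topological features.

A functional graph places an edge between two voxels when their Pearson
correlation (raw or absolute) strictly exceeds a threshold (default 0.7).
From the graph we derive per-voxel feature maps (degree in three flavors,
strength in three flavors, clustering coefficient, local efficiency),
six global summaries, and distance-resolved link statistics including a
power-law fit of link probability versus inter-voxel distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform

from .synthetic_cohort import BoldRun

__all__ = [
    "CorrelationStructure",
    "FunctionalGraph",
    "GlobalFeatures",
    "DistanceProfile",
    "pairwise_correlations",
    "sample_edges",
    "build_graph",
    "degree_maps",
    "strength_maps",
    "clustering_map",
    "local_efficiency_map",
    "global_features",
    "link_probability_by_distance",
    "fit_power_law",
    "interhemispheric_fraction",
    "roi_pair_link_fraction",
]

FULL_FORM_VOXEL_CAP = 6000  # above this, require an explicit pair list


@dataclass
class CorrelationStructure:
    """Pairwise Pearson correlations: full V x V matrix or a fixed pair sample."""

    coords_mm: np.ndarray  # V x 3
    coords_vox: np.ndarray  # V x 3
    full: np.ndarray | None = None  # V x V, diag 1
    pairs: np.ndarray | None = None  # P x 2 (i < j)
    pair_r: np.ndarray | None = None  # P
    constant_voxels: np.ndarray | None = None  # bool V, r defined as 0

    @property
    def n_voxels(self) -> int:
        return self.coords_mm.shape[0]


def pairwise_correlations(
    bold: BoldRun, pairs: np.ndarray | None = None
) -> CorrelationStructure:
    """Pearson correlations among masked voxel series.

    Full form when no pair list is given (and V is below the configured cap);
    sampled form over exactly the given (i, j) pairs otherwise.  Constant
    series get correlation 0 to all partners and are flagged.
    """
    series = bold.masked_series().astype(float)  # V x T
    v, t = series.shape
    if t < 3:
        raise ValueError("need at least 3 time points")
    sd = series.std(axis=1)
    constant = sd == 0.0
    coords_mm = bold.voxel_coords_mm()
    coords_vox = bold.voxel_coords_vox()

    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    unit = centered / safe[:, None]

    if pairs is None:
        if v > FULL_FORM_VOXEL_CAP:
            raise ValueError(
                f"{v} voxels exceeds the full-matrix cap ({FULL_FORM_VOXEL_CAP}); "
                "pass a sampled pair list"
            )
        full = unit @ unit.T
        np.clip(full, -1.0, 1.0, out=full)
        full[constant, :] = 0.0
        full[:, constant] = 0.0
        np.fill_diagonal(full, 1.0)
        return CorrelationStructure(
            coords_mm=coords_mm, coords_vox=coords_vox, full=full,
            constant_voxels=constant,
        )

    pairs = np.asarray(pairs, dtype=int)
    if pairs.size and (pairs.min() < 0 or pairs.max() >= v):
        raise ValueError("pair index outside the mask")
    r = np.einsum("pt,pt->p", unit[pairs[:, 0]], unit[pairs[:, 1]])
    np.clip(r, -1.0, 1.0, out=r)
    r[constant[pairs[:, 0]] | constant[pairs[:, 1]]] = 0.0
    return CorrelationStructure(
        coords_mm=coords_mm, coords_vox=coords_vox, pairs=pairs, pair_r=r,
        constant_voxels=constant,
    )


def sample_edges(n_voxels: int, n_pairs: int, seed: int) -> np.ndarray:
    """Uniform sample of unordered off-diagonal pairs, without replacement.

    The same seeded list must be reused for every sample in a study so that
    edge features are comparable across subjects.
    """
    total = n_voxels * (n_voxels - 1) // 2
    if n_pairs > total:
        raise ValueError(f"cannot sample {n_pairs} of {total} pairs")
    rng = np.random.default_rng(seed)
    lin = np.sort(rng.choice(total, size=n_pairs, replace=False))
    # invert the row-major upper-triangle linearization
    i = (
        n_voxels
        - 2
        - np.floor(
            np.sqrt(-8.0 * lin + 4.0 * n_voxels * (n_voxels - 1) - 7.0) / 2.0 - 0.5
        )
    ).astype(int)
    j = (lin - (i * (2 * n_voxels - i - 1)) // 2 + i + 1).astype(int)
    return np.column_stack([i, j])


@dataclass
class FunctionalGraph:
    """Undirected, unweighted graph over masked voxels."""

    adjacency: np.ndarray  # V x V bool, symmetric, no self-loops
    coords_mm: np.ndarray
    coords_vox: np.ndarray
    threshold: float
    mode: str  # "raw" | "absolute"
    hemisphere: np.ndarray = field(init=False)  # +1 right, -1 left, 0 midline

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape[0] != a.shape[1] or not np.array_equal(a, a.T):
            raise ValueError("adjacency must be square and symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.hemisphere = np.sign(self.coords_mm[:, 0]).astype(int)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def csr(self) -> csr_matrix:
        return csr_matrix(self.adjacency.astype(np.int8))


def build_graph(
    corr: CorrelationStructure, threshold: float = 0.7, mode: str = "raw"
) -> FunctionalGraph:
    """Edge (i, j) iff r_ij > threshold (raw) or |r_ij| > threshold (absolute);
    strictly greater in both modes."""
    if corr.full is None:
        raise ValueError("graph construction requires the full correlation form")
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    if mode not in ("raw", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    r = np.abs(corr.full) if mode == "absolute" else corr.full
    adj = r > threshold
    np.fill_diagonal(adj, False)
    return FunctionalGraph(
        adjacency=adj, coords_mm=corr.coords_mm, coords_vox=corr.coords_vox,
        threshold=threshold, mode=mode,
    )


def degree_maps(
    graph: FunctionalGraph, min_dist_voxels: float = 5.0, metric: str = "voxel"
) -> dict[str, np.ndarray]:
    """Full, long-distance, and inter-hemispheric degree per voxel.

    Long-distance counts neighbors at Euclidean distance >= min_dist_voxels
    in voxel-index units (mm units when ``metric="mm"``); inter-hemispheric
    counts neighbors on the opposite left/right side, never midline voxels.
    """
    coords = graph.coords_vox if metric == "voxel" else graph.coords_mm
    a = graph.adjacency
    dist = squareform(pdist(coords))
    hemi = graph.hemisphere
    opposite = hemi[:, None] * hemi[None, :] < 0  # midline (0) never qualifies
    return {
        "degree_full": a.sum(axis=1),
        "degree_long": (a & (dist >= min_dist_voxels)).sum(axis=1),
        "degree_interhemi": (a & opposite).sum(axis=1),
    }


def strength_maps(corr: CorrelationStructure) -> dict[str, np.ndarray]:
    """Signed, absolute, and positive-only sums of a voxel's correlations.

    Uses the full (unthresholded) correlation matrix as weighted adjacency.
    """
    if corr.full is None:
        raise ValueError("strength maps require the full correlation form")
    r = corr.full.copy()
    np.fill_diagonal(r, 0.0)
    return {
        "strength": r.sum(axis=1),
        "strength_abs": np.abs(r).sum(axis=1),
        "strength_pos": np.clip(r, 0.0, None).sum(axis=1),
    }


def clustering_map(graph: FunctionalGraph) -> np.ndarray:
    """Fraction of a node's neighbor pairs that are themselves linked
    (0 for degree < 2)."""
    a = graph.adjacency.astype(np.int64)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 2.0 * triangles / (k * (k - 1.0))
    c[k < 2] = 0.0
    return c


def _subgraph_efficiency(sub: np.ndarray) -> float:
    """Global efficiency of an unweighted graph given dense adjacency."""
    n = sub.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(csr_matrix(sub.astype(np.int8)), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency_map(graph: FunctionalGraph) -> np.ndarray:
    """Global efficiency of each node's neighborhood subgraph."""
    a = graph.adjacency
    out = np.zeros(graph.n_nodes)
    for v in range(graph.n_nodes):
        nb = np.flatnonzero(a[v])
        if nb.size < 2:
            continue
        out[v] = _subgraph_efficiency(a[np.ix_(nb, nb)])
    return out


@dataclass(frozen=True)
class GlobalFeatures:
    mean_degree: float
    mean_geodesic: float  # nan when no connected pair exists
    mean_clustering: float
    giant_component_size: int
    giant_component_ratio: float
    total_links: int


def global_features(graph: FunctionalGraph) -> GlobalFeatures:
    """Six global summaries; the mean geodesic averages over connected ordered
    pairs only (sparse thresholded networks are routinely disconnected)."""
    v = graph.n_nodes
    degrees = graph.degrees
    total_links = int(degrees.sum()) // 2
    if total_links == 0:
        return GlobalFeatures(0.0, float("nan"), 0.0, 1 if v else 0,
                              (1.0 / v) if v else 0.0, 0)
    n_comp, labels = connected_components(graph.csr(), directed=False)
    sizes = np.bincount(labels)
    giant = int(sizes.max())
    d = shortest_path(graph.csr(), method="D", unweighted=True)
    finite = np.isfinite(d) & ~np.eye(v, dtype=bool)
    mean_geo = float(d[finite].mean()) if finite.any() else float("nan")
    return GlobalFeatures(
        mean_degree=float(degrees.mean()),
        mean_geodesic=mean_geo,
        mean_clustering=float(clustering_map(graph).mean()),
        giant_component_size=giant,
        giant_component_ratio=giant / v,
        total_links=total_links,
    )


@dataclass
class DistanceProfile:
    bin_centers: np.ndarray  # mm
    link_probability: np.ndarray
    link_probability_sd: np.ndarray  # binomial sd per bin
    n_pairs: np.ndarray
    power_law: tuple[float, float] | None = None  # (a, gamma)
    fit_range: tuple[float, float] | None = None


def link_probability_by_distance(
    graph: FunctionalGraph, bin_width: float = 5.0
) -> DistanceProfile:
    """Per distance bin: (# linked pairs) / (# all pairs); empty bins omitted."""
    if graph.n_nodes < 2:
        raise ValueError("need at least 2 voxels")
    d = pdist(graph.coords_mm)
    iu = np.triu_indices(graph.n_nodes, k=1)
    linked = graph.adjacency[iu]
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    which = np.digitize(d, edges) - 1
    n_bins = len(edges) - 1
    totals = np.bincount(which, minlength=n_bins)
    hits = np.bincount(which, weights=linked.astype(float), minlength=n_bins)
    occupied = totals > 0
    p = hits[occupied] / totals[occupied]
    sd = np.sqrt(np.clip(p * (1 - p), 0.0, None) / totals[occupied])
    centers = (edges[:-1] + bin_width / 2.0)[occupied]
    return DistanceProfile(
        bin_centers=centers, link_probability=p, link_probability_sd=sd,
        n_pairs=totals[occupied],
    )


def fit_power_law(
    profile: DistanceProfile, d_min: float = 10.0, d_max: float = 150.0
) -> tuple[float, float]:
    """Least-squares fit of log p = log a - gamma * log d over bins with
    positive probability inside [d_min, d_max]; returns (a, gamma)."""
    sel = (
        (profile.bin_centers >= d_min)
        & (profile.bin_centers <= d_max)
        & (profile.link_probability > 0.0)
    )
    if sel.sum() < 3:
        raise ValueError("need at least 3 positive bins inside the fit range")
    logd = np.log(profile.bin_centers[sel])
    logp = np.log(profile.link_probability[sel])
    design = np.column_stack([np.ones(sel.sum()), -logd])
    (log_a, gamma), *_ = np.linalg.lstsq(design, logp, rcond=None)
    profile.power_law = (float(np.exp(log_a)), float(gamma))
    profile.fit_range = (d_min, d_max)
    return profile.power_law


def interhemispheric_fraction(graph: FunctionalGraph) -> float:
    """(# left-right links) / (# all links); midline-endpoint links count only
    in the denominator."""
    total = graph.n_edges
    if total == 0:
        raise ValueError("graph has no links")
    hemi = graph.hemisphere
    crossing = graph.adjacency & (hemi[:, None] * hemi[None, :] < 0)
    return float(crossing.sum() // 2) / total


def roi_pair_link_fraction(
    graph: FunctionalGraph, roi_a: np.ndarray, roi_b: np.ndarray
) -> float:
    """Fraction of all links with one endpoint in each (disjoint) ROI."""
    roi_a = np.asarray(roi_a, dtype=bool)
    roi_b = np.asarray(roi_b, dtype=bool)
    if (roi_a & roi_b).any():
        raise ValueError("ROIs must be disjoint")
    total = graph.n_edges
    if total == 0:
        raise ValueError("graph has no links")
    cross = graph.adjacency & (
        np.outer(roi_a, roi_b) | np.outer(roi_b, roi_a)
    )
    return float(cross.sum() // 2) / total
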