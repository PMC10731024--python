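"""Nuclei detection and Delaunay packing metrics on DAPI projections.

Proliferation and packing are read from nuclear centroids alone: nuclei
are detected as Laplacian-of-Gaussian blobs at the expected nuclear scale,
and tissue packing is summarized from a 2D Delaunay triangulation of the
centroids — the mean distance between neighboring nuclei and the mean
number of Delaunay neighbors per nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay
from skimage.feature import peak_local_max

from .core_io import InsufficientDataError


@dataclass
class NucleiSet:
    """Detected nuclear centroids in micrometres, with detection scores."""

    centroids_um: np.ndarray  # (N, 2) as (x, y)
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids_um = np.asarray(self.centroids_um, dtype=float).reshape(-1, 2)

    @property
    def n(self) -> int:
        return len(self.centroids_um)


@dataclass
class PackingMetrics:
    """Mean neighbor distance and neighbor count from the Delaunay graph."""

    mean_neighbor_distance_um: float
    mean_n_neighbors: float
    edges: np.ndarray  # (E, 2) indices into the centroid list
    max_edge_um: float | None = None
    fallback_pairwise: bool = False


def detect_nuclei(
    dapi_mip: np.ndarray,
    expected_diameter_um: float = 8.0,
    min_separation_um: float | None = None,
    pixel_size_um: float = 1.0,
    threshold_rel: float = 0.1,
) -> NucleiSet:
    """Blob detection of nuclei at the expected scale.

    The projection is filtered with a Laplacian-of-Gaussian matched to the
    expected nuclear diameter; local maxima separated by at least
    ``min_separation_um`` (default: half the diameter) and above
    ``threshold_rel`` of the strongest response become detections, refined
    to intensity-weighted centroids.  A blank image yields an empty set.
    """
    img = np.asarray(dapi_mip, dtype=float)
    if img.max() <= 0:
        return NucleiSet(np.empty((0, 2)), np.empty(0))
    if min_separation_um is None:
        min_separation_um = expected_diameter_um / 2.0
    sigma_px = expected_diameter_um / pixel_size_um / (2.0 * np.sqrt(2.0))
    response = -ndimage.gaussian_laplace(img, sigma_px) * sigma_px**2
    response[response < 0] = 0.0
    min_dist_px = max(1, int(round(min_separation_um / pixel_size_um)))
    peaks = peak_local_max(
        response, min_distance=min_dist_px, threshold_rel=threshold_rel, exclude_border=False
    )
    centroids = []
    scores = []
    w = max(1, int(round(sigma_px)))
    for r, c in peaks:
        r0, r1 = max(0, r - w), min(img.shape[0], r + w + 1)
        c0, c1 = max(0, c - w), min(img.shape[1], c + w + 1)
        patch = img[r0:r1, c0:c1]
        total = patch.sum()
        if total > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            cy = (rr * patch).sum() / total
            cx = (cc * patch).sum() / total
        else:
            cy, cx = float(r), float(c)
        centroids.append((cx * pixel_size_um, cy * pixel_size_um))
        scores.append(float(response[r, c]))
    return NucleiSet(np.array(centroids).reshape(-1, 2), np.array(scores))


def delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Unique undirected edges of the Delaunay triangulation of 2D points."""
    tri = Delaunay(points)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            edges.add((min(a, b), max(a, b)))
    return np.array(sorted(edges), dtype=int)


def delaunay_metrics(
    nuclei: NucleiSet | np.ndarray,
    max_edge_um: float | None = None,
) -> PackingMetrics:
    """Packing metrics from the Delaunay triangulation of nuclear centers.

    Per nucleus, the neighbor distance is the mean length of its incident
    Delaunay edges and the neighbor count its degree; the returned metrics
    average both over nuclei.  Edges longer than ``max_edge_um`` (convex
    hull artifacts) can be pruned; the default keeps all edges and records
    the choice.  Fewer than three non-collinear points fall back to the
    all-pairs graph with a warning; fewer than two points are undefined.
    """
    pts = nuclei.centroids_um if isinstance(nuclei, NucleiSet) else np.asarray(nuclei, float)
    pts = pts.reshape(-1, 2)
    n = len(pts)
    if n < 2:
        raise InsufficientDataError("packing metrics need at least 2 nuclei")

    def _pairwise() -> PackingMetrics:
        warnings.warn("degenerate point set; falling back to all-pairs distances")
        edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=int)
        return _metrics_from_edges(pts, edges, max_edge_um, fallback=True)

    if n < 3:
        return _pairwise()
    try:
        edges = delaunay_edges(pts)
    except Exception:  # collinear / degenerate input (scipy QhullError)
        return _pairwise()
    if edges.size == 0:
        return _pairwise()
    return _metrics_from_edges(pts, edges, max_edge_um, fallback=False)


def _metrics_from_edges(
    pts: np.ndarray, edges: np.ndarray, max_edge_um: float | None, fallback: bool
) -> PackingMetrics:
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    if max_edge_um is not None:
        keep = lengths <= max_edge_um
        edges, lengths = edges[keep], lengths[keep]
    n = len(pts)
    deg = np.zeros(n)
    dist_sum = np.zeros(n)
    for (a, b), d in zip(edges, lengths):
        deg[a] += 1
        deg[b] += 1
        dist_sum[a] += d
        dist_sum[b] += d
    connected = deg > 0
    if not connected.any():
        raise InsufficientDataError("edge pruning disconnected every nucleus")
    per_nucleus_dist = dist_sum[connected] / deg[connected]
    return PackingMetrics(
        mean_neighbor_distance_um=float(per_nucleus_dist.mean()),
        mean_n_neighbors=float(deg[connected].mean()),
        edges=edges,
        max_edge_um=max_edge_um,
        fallback_pairwise=fallback,
    )


def nuclei_timecourse(
    series: list[NucleiSet],
    max_edge_um: float | None = None,
) -> pd.DataFrame:
    """Counts and packing per timepoint, with ratios to the first timepoint."""
    rows = []
    for t, ns in enumerate(series):
        if ns.n >= 2:
            pm = delaunay_metrics(ns, max_edge_um=max_edge_um)
            dist, neigh = pm.mean_neighbor_distance_um, pm.mean_n_neighbors
        else:
            dist = neigh = float("nan")
        rows.append({"t": t, "count": ns.n, "mean_neighbor_distance_um": dist,
                     "mean_n_neighbors": neigh})
    df = pd.DataFrame(rows)
    df["count_ratio"] = df["count"] / df["count"].iloc[0] if df["count"].iloc[0] else np.nan
    d0 = df["mean_neighbor_distance_um"].iloc[0]
    df["distance_ratio"] = df["mean_neighbor_distance_um"] / d0 if d0 and np.isfinite(d0) else np.nan
    return df
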