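"""2D convex-hull geometry: denoising, hull construction, membership.

Coverage of one point cloud by another is always evaluated on a 2D
projection (one feature pair at a time); full-dimensional hulls of
clinical cohorts collapse under the curse of dimensionality, so the 2D
projections are the unit of analysis throughout the package.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DegenerateHullError",
    "Hull2D",
    "denoise_pair",
    "build_hull",
    "points_in_hull",
    "pair_coverage",
]

#: absolute tolerance for closed-polygon membership, on standardized coordinates
MEMBERSHIP_TOL = 1e-9


class DegenerateHullError(ValueError):
    """Fewer than 3 points, or all points collinear: no 2D hull exists."""


@dataclasses.dataclass(frozen=True)
class Hull2D:
    """Convex hull of a 2D point set.

    ``vertices`` are in counterclockwise order; ``equations`` are the
    outward half-plane normals ``(a, b, c)`` with ``a*x + b*y + c <= 0``
    for interior points, as produced by Qhull.
    """

    feature_pair: tuple[str, str]
    vertices: np.ndarray
    equations: np.ndarray

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")
    return pts


def _standardize(points: np.ndarray) -> np.ndarray:
    mu = points.mean(axis=0)
    sd = points.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (points - mu) / sd


def auto_eps(points: np.ndarray, min_samples: int = 5, quantile: float = 0.9) -> float:
    """Scale-free DBSCAN radius: a quantile of k-nearest-neighbor distances.

    Computed on z-scored coordinates so that heterogeneously scaled
    clinical features (e.g. FiO2 fractions next to platelet counts) get
    comparable density estimates. ``k = min_samples`` counts the point
    itself, matching DBSCAN's core-point rule.
    """
    z = _standardize(points)
    k = min(min_samples, len(z))
    nn = NearestNeighbors(n_neighbors=k).fit(z)
    dist, _ = nn.kneighbors(z)
    eps = float(np.quantile(dist[:, -1], quantile))
    return max(eps, 1e-12)


def denoise_pair(
    points,
    eps: float | None = None,
    min_samples: int = 5,
    eps_quantile: float = 0.9,
) -> np.ndarray:
    """Remove DBSCAN noise points before hull construction.

    Clustering runs on z-scored coordinates; ``eps`` (in standardized
    units) defaults to the ``eps_quantile`` quantile of distances to the
    ``min_samples``-th nearest neighbor. Points assigned to any density
    cluster are returned in their original coordinates.
    """
    pts = _as_points(points)
    if len(pts) == 0:
        raise ValueError("cannot denoise an empty point set")
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    z = _standardize(pts)
    if eps is None:
        eps = auto_eps(pts, min_samples=min_samples, quantile=eps_quantile)
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(z)
    keep = labels != -1
    if not keep.any():
        raise ValueError(
            "DBSCAN classified every point as noise; increase eps or "
            "decrease min_samples"
        )
    return pts[keep]


def build_hull(points, feature_pair: tuple[str, str] = ("x", "y")) -> Hull2D:
    """Convex hull (Quickhull) of a 2D point set, vertices counterclockwise."""
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateHullError(
            f"need at least 3 points for a 2D hull, got {len(pts)}"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(
            f"degenerate point set for pair {feature_pair}: {exc}"
        ) from exc
    return Hull2D(
        feature_pair=(str(feature_pair[0]), str(feature_pair[1])),
        vertices=pts[hull.vertices],
        equations=hull.equations,
    )


def points_in_hull(points, hull: Hull2D, tol: float = MEMBERSHIP_TOL) -> np.ndarray:
    """Boolean mask of points inside or on the hull (closed polygon).

    A point is inside iff it satisfies every half-plane inequality up to
    an absolute tolerance ``tol``.
    """
    pts = _as_points(points)
    margins = pts @ hull.equations[:, :2].T + hull.equations[:, 2]
    return margins.max(axis=1) <= tol


def pair_coverage(query, hull: Hull2D, tol: float = MEMBERSHIP_TOL) -> float:
    """Fraction of query points inside or on the hull.

    This is the directional coverage of a query dataset by the hull of a
    reference dataset for one feature pair; boundary points count as
    inside.
    """
    pts = _as_points(query)
    if len(pts) == 0:
        raise ValueError("cannot compute coverage of an empty query set")
    return float(points_in_hull(pts, hull, tol=tol).mean())
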