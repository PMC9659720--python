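"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: the
hull oracle enumerates candidate edges in O(n^2), membership is a
half-plane sign test around the ordered polygon, and the onset oracle
scans every measurement as a candidate onset time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hullshift import CohortTable


# ---------------------------------------------------------------------------
# geometry oracles
# ---------------------------------------------------------------------------

def brute_force_hull_indices(pts: np.ndarray) -> set[int]:
    """O(n^2) convex-hull vertex set: edge (i, j) is on the hull iff every
    other point lies on its left; hull vertices are the edge endpoints."""
    n = len(pts)
    verts: set[int] = set()
    for i in range(n):
        d = pts - pts[i]
        # C[j, k] = cross(p_j - p_i, p_k - p_i)
        C = np.outer(d[:, 0], d[:, 1]) - np.outer(d[:, 1], d[:, 0])
        edges = (C >= 0).all(axis=1)
        for j in np.flatnonzero(edges):
            if j != i:
                verts.add(i)
                verts.add(int(j))
    return verts


def order_polygon_ccw(pts: np.ndarray) -> np.ndarray:
    """Order hull vertices counterclockwise around their centroid."""
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    return pts[np.argsort(ang)]


def points_in_polygon_sign_test(
    points: np.ndarray, polygon_ccw: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """Half-plane sign test: inside iff left of (or on) every CCW edge."""
    inside = np.ones(len(points), dtype=bool)
    n = len(polygon_ccw)
    for k in range(n):
        a = polygon_ccw[k]
        b = polygon_ccw[(k + 1) % n]
        cross = (b[0] - a[0]) * (points[:, 1] - a[1]) - (b[1] - a[1]) * (
            points[:, 0] - a[0]
        )
        inside &= cross >= -tol
    return inside


# ---------------------------------------------------------------------------
# onset oracle
# ---------------------------------------------------------------------------

def brute_force_onset(times, values, threshold=300.0, sustain_h=24.0):
    """Exhaustive candidate scan: a measurement time t qualifies as onset
    iff its value is below threshold, every measurement within
    [t, t + sustain_h] is below threshold, and the record extends at
    least sustain_h beyond t. Returns the earliest qualifying time."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    for i in range(len(t)):
        if v[i] >= threshold:
            continue
        if t[-1] - t[i] < sustain_h:
            continue
        window = (t >= t[i]) & (t <= t[i] + sustain_h)
        if (v[window] < threshold).all():
            return float(t[i])
    return None


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_cohort(site_id: str, values: np.ndarray, features=None, endpoint=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{j:02d}" for j in range(values.shape[1])]
    idx = pd.Index([f"{site_id}-{i}" for i in range(len(values))], name="patient_id")
    ep = pd.Series(endpoint, index=idx) if endpoint is not None else None
    return CohortTable(site_id, pd.DataFrame(values, index=idx, columns=features), ep)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_feature_cohorts(rng):
    """Two 2-feature cohorts drawn from the same standard normal."""
    a = make_cohort("A", rng.normal(size=(200, 2)), features=["x", "y"])
    b = make_cohort("B", rng.normal(size=(200, 2)), features=["x", "y"])
    return a, b
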