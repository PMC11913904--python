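"""Shared low-level geometry: clearances, plane fits, rigid superposition."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def surface_clearance(points: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                      tree: cKDTree | None = None) -> np.ndarray:
    """Distance from each query point to the nearest atom *surface*.

    clearance(p) = min_i ( ||p - c_i|| - r_i ).  With heterogeneous radii the
    nearest center need not give the minimum, so neighbours within the radius
    spread of the nearest-center distance are also examined.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    radii = np.asarray(radii, dtype=float)
    if tree is None:
        tree = cKDTree(centers)
    d1, i1 = tree.query(points, k=1)
    clear = d1 - radii[i1]
    spread = radii.max() - radii.min()
    if spread > 1e-12:
        # any atom beating the current best lies within d1 + r_max of the point
        pairs = tree.query_ball_point(points, d1 + radii.max() + 1e-9)
        for k, idx in enumerate(pairs):
            idx = np.asarray(idx, dtype=int)
            d = np.linalg.norm(centers[idx] - points[k], axis=1) - radii[idx]
            clear[k] = d.min()
    return clear


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through ``points``.

    Returns (centroid, unit normal) where the normal is the eigenvector of the
    centered covariance with the smallest eigenvalue.  Raises on (near-)
    collinear input, for which the plane is not unique.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    x = pts - centroid
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[1] <= max(s[0], 1.0) * 1e-10:
        raise ValueError("plane fit is degenerate: points are collinear")
    normal = vt[-1]
    return centroid, normal / np.linalg.norm(normal)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with R @ (mobile - com) + t ~= reference.

    Returns (R, t) such that ``mobile @ R.T + t`` superposes onto reference in
    the least-squares sense.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    com_m = mob.mean(axis=0)
    com_r = ref.mean(axis=0)
    h = (mob - com_m).T @ (ref - com_r)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = com_r - rot @ com_m
    return rot, trans


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in radians for four points (IUPAC convention)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.arctan2(y, x))


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n
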