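"""Shared geometry helpers: minimum-image distances, dihedrals, rotations."""

from __future__ import annotations

import numpy as np

__all__ = ["delta", "distance_matrix", "min_dist", "dihedral", "angle", "rotate_about_axis"]


def delta(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> np.ndarray:
    """Pairwise displacement vectors a[i] - b[j], minimum image if box given.

    Returns an ``(len(a), len(b), 3)`` array.  The minimum-image convention
    is applied per axis for orthorhombic boxes only (the supported box type).
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        box = np.asarray(box, dtype=float)
        for k in range(3):
            if box[k] > 0:
                d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    return d


def distance_matrix(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> np.ndarray:
    """Pairwise distances (len(a), len(b)), minimum image if box given."""
    d = delta(a, b, box)
    return np.sqrt((d * d).sum(axis=-1))


def min_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> float:
    """Minimum pairwise distance between two point sets."""
    return float(distance_matrix(a, b, box).min())


def angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = p0 - p1
    v2 = p2 - p1
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate points by angle_deg about the (unit-normalized) axis through origin."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    k = axis
    p = points - origin
    # Rodrigues rotation formula
    rot = (
        p * np.cos(theta)
        + np.cross(k, p) * np.sin(theta)
        + np.outer(p @ k, k) * (1.0 - np.cos(theta))
    )
    return rot + origin
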