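"""Minimum-image geometry helpers for orthorhombic periodic boxes.

All distances in the package funnel through these functions so that the
periodic convention (nearest image per axis, non-periodic axes untouched)
is applied uniformly.
"""
from __future__ import annotations

import numpy as np


def minimum_image(disp: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Map displacement vectors to their nearest periodic image.

    Parameters
    ----------
    disp : (..., 3) array of raw displacement vectors (Å).
    box : (3,) box edge lengths (Å), orthorhombic.
    periodic : (3,) booleans; axes flagged False are left as-is.
    """
    disp = np.asarray(disp, dtype=float)
    box = np.asarray(box, dtype=float)
    shift = np.round(disp / box) * box
    return disp - np.where(np.asarray(periodic, bool), shift, 0.0)


def pair_distances(a: np.ndarray, b: np.ndarray, box, periodic) -> np.ndarray:
    """All minimum-image distances between two point sets: (len(a), len(b))."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    d = minimum_image(b[None, :, :] - a[:, None, :], box, periodic)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def distance(a, b, box, periodic) -> float:
    """Minimum-image distance between two points."""
    d = minimum_image(np.asarray(b, float) - np.asarray(a, float), box, periodic)
    return float(np.linalg.norm(d))


def wrap(coords: np.ndarray, box, periodic) -> np.ndarray:
    """Wrap coordinates into [0, box) along periodic axes."""
    coords = np.asarray(coords, float).copy()
    box = np.asarray(box, float)
    per = np.asarray(periodic, bool)
    coords[..., per] = np.mod(coords[..., per], box[per])
    return coords


def random_unit_vector(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniformly distributed unit vector(s) on the sphere."""
    size = (3,) if n is None else (n, 3)
    v = rng.normal(size=size)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``a`` onto unit vector ``b`` (Rodrigues)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = _skew(axis)
        return np.eye(3) + 2.0 * (K @ K)
    vx = _skew(v)
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], float)
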