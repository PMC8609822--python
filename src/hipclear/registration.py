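"""Rigid registration: Kabsch fits and point-to-point ICP.

The ICP variant alternates nearest-neighbour correspondence (KD-tree) with
the closed-form SVD least-squares rigid update, the classic scheme for
registering the same bone imaged in two postures. It is point-to-point, has
no scale estimation, and by default no outlier trimming (an optional
worst-fraction trim is exposed for partial-overlap scans).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, InputError
from .geometry import PointCloud, RigidTransform


def kabsch(source: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares rigid transform mapping `source` points onto `target`.

    Standard centroid + SVD solution with a reflection guard (the sign of the
    smallest singular vector is flipped if the optimum would be improper).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise InputError("kabsch needs matching (n, 3) arrays")
    if src.shape[0] < 3:
        raise DegenerateGeometryError("rigid fit needs at least 3 correspondences")
    if weights is None:
        w = np.ones(len(src))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    sc = w @ src
    tc = w @ tgt
    H = (src - sc).T @ ((tgt - tc) * w[:, None])
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    return RigidTransform(R, t)


@dataclass(frozen=True)
class ICPResult:
    transform: RigidTransform
    rms_distance: float
    iterations: int
    converged: bool
    rms_history: tuple = ()  # RMS after each iteration (non-increasing)


def icp_register(
    source: PointCloud,
    target: PointCloud,
    max_iter: int = 200,
    tol: float = 1e-4,
    init: RigidTransform | None = None,
    trim_fraction: float = 0.0,
) -> ICPResult:
    """Point-to-point ICP mapping `source` into the frame of `target`.

    Iterates until the change in RMS nearest-neighbour distance falls below
    `tol` (mm) or `max_iter` is reached; in the latter case the result is
    still returned with ``converged=False`` and the caller decides.
    `trim_fraction` discards that worst fraction of correspondences in each
    update (default 0: the plain algorithm).
    """
    if len(source) < 10 or len(target) < 10:
        raise InputError("ICP needs at least 10 points in each cloud")
    if not tol > 0:
        raise InputError("tol must be positive")
    if not 0.0 <= trim_fraction < 1.0:
        raise InputError("trim_fraction must be in [0, 1)")

    tree = cKDTree(target.points)
    transform = init if init is not None else RigidTransform.identity()
    moved = transform.apply(source.points)
    prev_rms = np.inf
    rms = np.inf
    iterations = 0
    converged = False
    keep = max(3, int(np.ceil(len(source) * (1.0 - trim_fraction))))
    history = []

    for iterations in range(1, max_iter + 1):
        dists, idx = tree.query(moved)
        if trim_fraction > 0.0:
            order = np.argsort(dists)[:keep]
        else:
            order = slice(None)
        step = kabsch(moved[order], target.points[idx][order])
        transform = step @ transform
        moved = transform.apply(source.points)
        dists, _ = tree.query(moved)
        if trim_fraction > 0.0:
            rms = float(np.sqrt(np.mean(np.sort(dists)[:keep] ** 2)))
        else:
            rms = float(np.sqrt(np.mean(dists**2)))
        history.append(rms)
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms

    return ICPResult(
        transform=transform,
        rms_distance=rms,
        iterations=iterations,
        converged=converged,
        rms_history=tuple(history),
    )


def apply_registration(cloud: PointCloud, transform: RigidTransform) -> PointCloud:
    """Map every point p -> R p + t, preserving the label."""
    return cloud.transformed(transform)


def landmark_align(source_landmarks: dict, target_landmarks: dict) -> RigidTransform:
    """Pre-alignment from named landmark correspondences (helper for large
    posture changes before ICP). Uses the labels common to both sets."""
    names = sorted(set(source_landmarks) & set(target_landmarks))
    if len(names) < 3:
        raise InputError("landmark alignment needs at least 3 shared landmarks")
    src = np.array([source_landmarks[n] for n in names], dtype=float)
    tgt = np.array([target_landmarks[n] for n in names], dtype=float)
    return kabsch(src, tgt)
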