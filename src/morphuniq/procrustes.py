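"""Generalized least-squares Procrustes superimposition (GPA).

Full-Procrustes convention: every configuration is centred and scaled to
unit centroid size, then rotated onto the running consensus by orthogonal
least squares with the determinant constrained positive (no reflection —
left and right mandibles are analysed separately, so mirror alignment is
never wanted).  The consensus is the mean of the aligned configurations,
re-scaled to unit centroid size each iteration.  After convergence the whole
set is rotated so the consensus principal axes coincide with the coordinate
axes, making the output orientation reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import LandmarkConfiguration, LandmarkDataset

logger = logging.getLogger(__name__)


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide (zero centroid size)."""


def centroid_size(coords: np.ndarray | LandmarkConfiguration) -> float:
    """Square root of summed squared landmark distances from the centroid.

    Invariant to translation and rotation; scales linearly under isotropic
    scaling.  For a :class:`LandmarkConfiguration` the physical-unit (scaled)
    coordinates are used.
    """
    if isinstance(coords, LandmarkConfiguration):
        coords = coords.scaled_coords()
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need k >= 3 landmarks")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincident")
    return cs


def _center_and_scale(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    cs = np.sqrt((centred**2).sum())
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincident")
    return centred / cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det = +1) minimising ||source @ R - target||_F.

    Closed-form orthogonal fit via SVD of the cross-covariance, with the
    smallest singular direction sign-flipped when the unconstrained optimum
    would be a reflection.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, d])
    return u @ flip @ vt


@dataclass
class ProcrustesResult:
    aligned: np.ndarray  # (n, k, 2), unit centroid size each
    consensus: np.ndarray  # (k, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,), original physical units
    iterations: int
    converged: bool
    specimen_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def residual_ss(self) -> float:
        return float(((self.aligned - self.consensus) ** 2).sum())


def _principal_axis_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation taking the consensus onto its principal axes, sign-fixed."""
    cov = consensus.T @ consensus
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    rot = vecs[:, order]
    if np.linalg.det(rot) < 0:
        rot[:, 1] = -rot[:, 1]
    aligned = consensus @ rot
    # deterministic sign: largest-|x| landmark gets positive x, same for y
    for axis in (0, 1):
        j = np.argmax(np.abs(aligned[:, axis]))
        if aligned[j, axis] < 0:
            rot[:, axis] = -rot[:, axis]
            aligned = consensus @ rot
    if np.linalg.det(rot) < 0:  # sign fixes may reintroduce a reflection
        rot[:, 1] = -rot[:, 1]
    return rot


def gpa_align(
    dataset: LandmarkDataset | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Iterative GPA of a dataset (or raw ``(n, k, 2)`` array).

    The residual sum of squared distances to the consensus is non-increasing
    across iterations; iteration stops when the consensus moves by less than
    ``tol`` (root-mean-square landmark displacement).
    """
    ids = None
    if isinstance(dataset, LandmarkDataset):
        arr = dataset.coord_array(scaled=True)
        ids = dataset.specimen_ids
    else:
        arr = np.asarray(dataset, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("need at least 2 configurations of shape (k, 2)")
    sizes = np.array([centroid_size(c) for c in arr])
    aligned = np.stack([_center_and_scale(c) for c in arr])

    # initial consensus: mean of the centred/scaled set, falling back to the
    # first configuration when random orientations cancel the mean out
    raw_mean = aligned.mean(axis=0)
    if np.sqrt((raw_mean**2).sum()) > 1e-3:
        consensus = _center_and_scale(raw_mean)
    else:
        consensus = aligned[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(aligned.shape[0]):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        new_consensus = _center_and_scale(aligned.mean(axis=0))
        shift = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)

    rot = _principal_axis_rotation(consensus)
    consensus = consensus @ rot
    aligned = aligned @ rot
    # one final rotation pass so every specimen is optimally posed w.r.t.
    # the reported consensus
    for i in range(aligned.shape[0]):
        aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
    return ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=it,
        converged=converged,
        specimen_ids=ids,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two shapes (no reflection).

    Both configurations are centred and scaled to unit centroid size, b is
    rotated onto a, and the optimal residual uses the closed form
    ``sqrt(1 - s²)`` with ``s`` the constrained-rotation correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    za = _center_and_scale(a)
    zb = _center_and_scale(b)
    _, svals, _ = np.linalg.svd(za.T @ zb)
    det = np.linalg.det(za.T @ zb)
    s = svals[0] + np.sign(det) * svals[1]
    s = min(s, 1.0)
    return float(np.sqrt(max(0.0, 1.0 - s**2)))
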