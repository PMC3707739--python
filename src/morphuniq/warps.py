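"""Thin-plate-spline decomposition of aligned shapes.

From a GPA consensus the TPS kernel U(r) = r² log r² yields a bending-energy
matrix whose non-null eigenvectors are the principal warps.  A specimen's
deviation from the consensus is projected onto the principal warps (one x
and one y score per warp) and onto a two-dimensional uniform (affine) basis,
giving 2k − 4 shape variables per specimen — 16 partial-warp scores plus two
uniform components for the k = 11 mandible design.  Relative warps are the
unweighted principal components of those shape variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .procrustes import ProcrustesResult


class CoincidentLandmarksError(ValueError):
    pass


def tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U as a function of squared distance: r² log(r²), 0 at r = 0."""
    out = np.zeros_like(r2, dtype=float)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


def bending_energy_matrix(consensus: np.ndarray) -> np.ndarray:
    """k×k bending-energy matrix of the TPS anchored at the consensus.

    Upper-left block of the inverse of the bordered system
    ``[[K, P], [Pᵀ, 0]]`` with ``P = [1 | x | y]``; symmetric PSD with an
    exactly 3-dimensional null space (the affine functions 1, x, y).
    """
    x = np.asarray(consensus, dtype=float)
    k = x.shape[0]
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    if np.any(d2[~np.eye(k, dtype=bool)] == 0):
        raise CoincidentLandmarksError("coincident landmarks in consensus")
    kmat = tps_kernel(d2)
    p = np.column_stack([np.ones(k), x])
    l = np.zeros((k + 3, k + 3))
    l[:k, :k] = kmat
    l[:k, k:] = p
    l[k:, :k] = p.T
    be = np.linalg.inv(l)[:k, :k]
    return (be + be.T) / 2.0


@dataclass
class ShapeBasis:
    """Orthonormal basis of the 2k−4 dimensional shape-variable space."""

    consensus: np.ndarray  # (k, 2)
    bending_energy: np.ndarray  # (k, k)
    principal_warps: np.ndarray  # (k, k-3) columns, orthonormal
    warp_eigenvalues: np.ndarray  # (k-3,) decreasing, > 0
    uniform_basis: np.ndarray  # (2k, 2) columns, orthonormal displacement fields
    basis_matrix: np.ndarray  # (2k, 2k-4): PW1x, PW1y, …, U1, U2

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    @property
    def n_variables(self) -> int:
        return self.basis_matrix.shape[1]

    def variable_names(self) -> list[str]:
        names = []
        for j in range(self.principal_warps.shape[1]):
            names += [f"PW{j + 1}x", f"PW{j + 1}y"]
        return names + ["U1", "U2"]


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    j = np.argmax(np.abs(vec))
    return vec if vec[j] >= 0 else -vec


def build_shape_basis(consensus: np.ndarray) -> ShapeBasis:
    """Principal warps + uniform components from a consensus configuration.

    Principal warps are the k−3 positive-eigenvalue eigenvectors of the
    bending-energy matrix, ordered by decreasing eigenvalue with the
    largest-magnitude loading made positive.  The uniform basis spans the
    affine displacement fields of the consensus orthogonalised against the
    similarity fields (translation, rotation, scaling) — the orthogonal-
    complement construction.
    """
    x = np.asarray(consensus, dtype=float)
    x = x - x.mean(axis=0)
    k = x.shape[0]
    if k < 4:
        raise ValueError("need k >= 4 landmarks for a nontrivial basis")
    be = bending_energy_matrix(x)
    vals, vecs = np.linalg.eigh(be)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pw_vals = vals[: k - 3]
    pw = vecs[:, : k - 3]
    pw = np.column_stack([_fix_sign(pw[:, j]) for j in range(k - 3)])

    # similarity fields to remove: translation x/y, scaling, rotation
    def vec2(field: np.ndarray) -> np.ndarray:
        return field.reshape(-1)

    sim = np.column_stack(
        [
            vec2(np.column_stack([np.ones(k), np.zeros(k)])),
            vec2(np.column_stack([np.zeros(k), np.ones(k)])),
            vec2(x),  # scaling
            vec2(np.column_stack([-x[:, 1], x[:, 0]])),  # rotation
        ]
    )
    q_sim, _ = np.linalg.qr(sim)
    # affine candidates: symmetric traceless 2x2 actions (stretch + shear)
    cand = np.column_stack(
        [
            vec2(np.column_stack([x[:, 0], -x[:, 1]])),
            vec2(np.column_stack([x[:, 1], x[:, 0]])),
        ]
    )
    cand = cand - q_sim @ (q_sim.T @ cand)
    q_uni, _ = np.linalg.qr(cand)
    q_uni = np.column_stack([_fix_sign(q_uni[:, j]) for j in range(2)])

    cols = []
    for j in range(k - 3):
        for axis in (0, 1):
            field = np.zeros((k, 2))
            field[:, axis] = pw[:, j]
            cols.append(field.reshape(-1))
    cols.append(q_uni[:, 0])
    cols.append(q_uni[:, 1])
    basis = np.column_stack(cols)
    return ShapeBasis(
        consensus=x,
        bending_energy=be,
        principal_warps=pw,
        warp_eigenvalues=pw_vals,
        uniform_basis=q_uni,
        basis_matrix=basis,
    )


@dataclass
class ShapeVariables:
    """Per-specimen partial-warp + uniform scores (n × (2k−4))."""

    scores: np.ndarray
    basis: ShapeBasis
    specimen_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Landmark deviations from the consensus implied by the scores."""
        dev = self.scores @ self.basis.basis_matrix.T
        return dev.reshape(self.n, self.basis.k, 2)


def shape_variables(result: ProcrustesResult, basis: ShapeBasis) -> ShapeVariables:
    """Project each aligned specimen's deviation onto the shape basis."""
    if result.consensus.shape != basis.consensus.shape or not np.allclose(
        result.consensus - result.consensus.mean(0), basis.consensus, atol=1e-6
    ):
        raise ValueError("basis was built on a different consensus")
    dev = (result.aligned - result.consensus).reshape(result.n, -1)
    scores = dev @ basis.basis_matrix
    return ShapeVariables(scores=scores, basis=basis, specimen_ids=result.specimen_ids)


@dataclass
class RelativeWarps:
    """Unweighted PCA of shape variables (α = 0)."""

    scores: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,) non-increasing, >= 0
    percent_variance: np.ndarray  # sums to 100
    loadings: np.ndarray  # (m, m) orthonormal columns
    mean: np.ndarray  # (m,) shape-variable mean removed before projection
    specimen_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def m(self) -> int:
        return self.scores.shape[1]


def relative_warps(shape_vars: ShapeVariables | np.ndarray, specimen_ids=None) -> RelativeWarps:
    """Centered, unweighted PCA: eigendecomposition of the sample covariance.

    Eigenvalues equal the sample variances (ddof = 1) of the corresponding
    scores; percent variance is normalised to sum to 100.
    """
    if isinstance(shape_vars, ShapeVariables):
        mat = shape_vars.scores
        specimen_ids = specimen_ids or shape_vars.specimen_ids
    else:
        mat = np.asarray(shape_vars, dtype=float)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need n >= 2 specimens")
    mean = mat.mean(axis=0)
    centred = mat - mean
    cov = centred.T @ centred / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    total = vals.sum()
    if total <= 0:
        raise ValueError("zero total shape variance")
    vecs = np.column_stack([_fix_sign(vecs[:, j]) for j in range(vecs.shape[1])])
    scores = centred @ vecs
    return RelativeWarps(
        scores=scores,
        eigenvalues=vals,
        percent_variance=100.0 * vals / total,
        loadings=vecs,
        mean=mean,
        specimen_ids=specimen_ids,
    )


def rw_regression_direction(
    shape_vars: ShapeVariables | np.ndarray, rw_scores: np.ndarray
) -> np.ndarray:
    """Shape-change direction from simple regressions of each shape variable
    on one relative-warp score vector (slopes assembled into an m-vector)."""
    mat = shape_vars.scores if isinstance(shape_vars, ShapeVariables) else np.asarray(shape_vars)
    s = np.asarray(rw_scores, dtype=float)
    if s.shape[0] != mat.shape[0]:
        raise ValueError("score length mismatch")
    sc = s - s.mean()
    denom = (sc**2).sum()
    if denom == 0:
        raise ValueError("zero-variance scores")
    centred = mat - mat.mean(axis=0)
    return centred.T @ sc / denom


def tps_interpolant(source: np.ndarray, target: np.ndarray):
    """Exact TPS map of the plane taking source landmarks to target ones.

    Returns a callable evaluating the interpolant at (q, 2) query points.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    k = src.shape[0]
    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    kmat = tps_kernel(d2)
    p = np.column_stack([np.ones(k), src])
    l = np.zeros((k + 3, k + 3))
    l[:k, :k] = kmat
    l[:k, k:] = p
    l[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    coefs = np.linalg.solve(l, rhs)
    w, a = coefs[:k], coefs[k:]

    def apply(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2q = ((pts[:, None, :] - src[None, :, :]) ** 2).sum(-1)
        u = tps_kernel(d2q)
        return a[0] + pts @ a[1:] + u @ w

    return apply


def deformation_grid(
    basis: ShapeBasis,
    direction: np.ndarray,
    magnitude: float,
    grid_shape: tuple[int, int] = (20, 20),
    margin: float = 0.1,
) -> np.ndarray:
    """Regular grid over the consensus warped along a shape-variable direction.

    ``direction`` lives in shape-variable space (an RW loading or a
    regression direction); the implied landmark displacement is
    ``magnitude × (basis @ direction)`` and the grid is carried along by the
    TPS interpolant.  Magnitude 0 returns the undeformed grid.
    """
    if not np.isfinite(magnitude):
        raise ValueError("magnitude must be finite")
    direction = np.asarray(direction, dtype=float)
    disp = (basis.basis_matrix @ direction).reshape(basis.k, 2) * magnitude
    target = basis.consensus + disp
    lo = basis.consensus.min(axis=0)
    hi = basis.consensus.max(axis=0)
    span = hi - lo
    lo, hi = lo - margin * span, hi + margin * span
    rows, cols = grid_shape
    gy, gx = np.meshgrid(
        np.linspace(lo[1], hi[1], rows), np.linspace(lo[0], hi[0], cols), indexing="ij"
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if magnitude == 0:
        return pts.reshape(rows, cols, 2)
    warped = tps_interpolant(basis.consensus, target)(pts)
    return warped.reshape(rows, cols, 2)
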