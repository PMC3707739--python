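"""Morphological Uniqueness (MU): kernel-density morphospace partitioning.

Along each relative warp the two groups' score distributions are turned
into Gaussian kernel densities, both densities are evaluated on one common
grid and renormalised to integrate to 1, and the overlap is the integral of
their pointwise minimum.  Uniqueness along a warp is one minus that
overlap; the per-warp uniqueness values are weighted by each warp's
eigenvalue proportion of total variance and summed, giving an overall MU
in [0, 1].  Significance comes from re-assigning specimens to groups of the
original sizes (with replacement by default) and recomputing MU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .warps import RelativeWarps

logger = logging.getLogger(__name__)

_SQRT2PI = np.sqrt(2.0 * np.pi)


class ZeroVarianceGroupError(ValueError):
    """A group has zero within-group variance: a kernel density is degenerate.

    Jitter the scores or collapse exact ties before calling."""


def silverman_bandwidth(x: np.ndarray) -> float:
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise ZeroVarianceGroupError("zero within-group variance")
    return 0.9 * spread * x.size ** (-0.2)


def sheather_jones_bandwidth(x: np.ndarray) -> float:
    """Plug-in bandwidth (Sheather–Jones style, normal-reference pilot)."""
    n = x.size
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ZeroVarianceGroupError("zero within-group variance")
    # two-stage normal-scale plug-in estimate of the roughness of f''
    g = 1.241 * sd * n ** (-1 / 7)
    d = x[:, None] - x[None, :]
    u = d / g
    phi4 = (u**4 - 6 * u**2 + 3) * np.exp(-0.5 * u**2) / _SQRT2PI
    rf2 = phi4.sum() / (n * (n - 1) * g**5)
    rf2 = max(rf2, 1e-12)
    return float((1.0 / (2 * np.sqrt(np.pi) * rf2 * n)) ** 0.2)


_BANDWIDTHS = {"silverman": silverman_bandwidth, "sheather_jones": sheather_jones_bandwidth}


def _bandwidths_batch(x: np.ndarray) -> np.ndarray:
    """Silverman bandwidths row-wise for an (R, n) batch."""
    sd = x.std(axis=1, ddof=1)
    q75, q25 = np.percentile(x, [75, 25], axis=1)
    iqr = (q75 - q25) / 1.349
    spread = np.where(iqr > 0, np.minimum(sd, iqr), sd)
    if np.any(spread <= 0):
        raise ZeroVarianceGroupError("zero within-group variance in a resample")
    return 0.9 * spread * x.shape[1] ** (-0.2)


def _overlap_batch(
    a: np.ndarray,
    b: np.ndarray,
    range_rule: str = "union_extended",
    grid_points: int = 512,
    bw_a: np.ndarray | None = None,
    bw_b: np.ndarray | None = None,
) -> np.ndarray:
    """Row-wise KDE overlap for batches a: (R, na), b: (R, nb)."""
    if bw_a is None:
        bw_a = _bandwidths_batch(a)
    if bw_b is None:
        bw_b = _bandwidths_batch(b)
    hmax = np.maximum(bw_a, bw_b)
    if range_rule == "union_extended":
        lo = np.minimum(a.min(axis=1), b.min(axis=1)) - 3 * hmax
        hi = np.maximum(a.max(axis=1), b.max(axis=1)) + 3 * hmax
    elif range_rule == "largest_group":
        big, small = (a, b) if a.shape[1] >= b.shape[1] else (b, a)
        lo = big.min(axis=1)
        hi = big.max(axis=1)
    else:
        raise ValueError(f"unknown range_rule {range_rule!r}")
    t = np.linspace(0.0, 1.0, grid_points)
    grid = (lo[:, None] + (hi - lo)[:, None] * t).astype(np.float32)  # (R, G)
    dx = (hi - lo) / (grid_points - 1)

    def density(x: np.ndarray, h: np.ndarray) -> np.ndarray:
        # kernel sums in float32, in place: the KDE statistical error dwarfs
        # the arithmetic error and the batch is an order of magnitude faster
        z = grid[:, :, None] - x.astype(np.float32)[:, None, :]
        z *= (1.0 / h.astype(np.float32))[:, None, None]
        np.multiply(z, z, out=z)
        z *= -0.5
        np.exp(z, out=z)
        f = z.sum(axis=2, dtype=np.float64)
        # renormalise on the grid so the overlap stays in [0, 1] under any range rule
        area = np.trapezoid(f, dx=1.0, axis=1)
        return f / np.maximum(area, 1e-300)[:, None]

    fa = density(a, bw_a)
    fb = density(b, bw_b)
    # densities are normalised to unit *grid* integral, so dx cancels
    ov = np.trapezoid(np.minimum(fa, fb), dx=1.0, axis=1)
    return np.clip(ov, 0.0, 1.0)


def rw_overlap(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    bandwidth_rule: str = "silverman",
    range_rule: str = "union_extended",
    grid_points: int = 512,
) -> float:
    """Kernel-density overlap of two univariate score samples, in [0, 1]."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    bw = _BANDWIDTHS[bandwidth_rule]
    ov = _overlap_batch(
        a[None, :],
        b[None, :],
        range_rule=range_rule,
        grid_points=grid_points,
        bw_a=np.array([bw(a)]),
        bw_b=np.array([bw(b)]),
    )
    return float(ov[0])


def rw_uniqueness(scores_a, scores_b, **kwargs) -> float:
    """Unity minus the kernel-density overlap along one relative warp."""
    return 1.0 - rw_overlap(scores_a, scores_b, **kwargs)


@dataclass
class MUResult:
    rw_uniqueness: np.ndarray  # (m,) in [0, 1]
    weights: np.ndarray  # (m,) eigenvalue proportions, sum 1
    overall_mu: float
    group_sizes: tuple[int, int]
    p_value: float | None = None
    n_resamples: int = 0
    null_mean: float | None = None
    null_quantiles: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert np.all((self.rw_uniqueness >= 0) & (self.rw_uniqueness <= 1))
        assert 0.0 <= self.overall_mu <= 1.0


def _mu_from_matrix(
    scores: np.ndarray,
    weights: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    **kwargs,
) -> tuple[np.ndarray, float]:
    u = np.empty(scores.shape[1])
    for j in range(scores.shape[1]):
        u[j] = 1.0 - rw_overlap(scores[mask_a, j], scores[mask_b, j], **kwargs)
    return u, float(np.clip(weights @ u, 0.0, 1.0))


def _two_level_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    return labels == levels[0], labels == levels[1], levels


def overall_mu(
    relwarps: RelativeWarps,
    labels: np.ndarray,
    n_rws: int | None = None,
    **kwargs,
) -> MUResult:
    """Eigenvalue-weighted sum of per-RW uniqueness between two groups.

    ``n_rws`` restricts to the leading warps (weights renormalised); the
    default uses every warp with positive eigenvalue.
    """
    mask_a, mask_b, _ = _two_level_masks(labels)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("need n >= 3 per group")
    scores, weights = _scores_and_weights(relwarps, n_rws)
    u, mu = _mu_from_matrix(scores, weights, mask_a, mask_b, **kwargs)
    return MUResult(
        rw_uniqueness=u,
        weights=weights,
        overall_mu=mu,
        group_sizes=(int(mask_a.sum()), int(mask_b.sum())),
    )


def _scores_and_weights(relwarps: RelativeWarps, n_rws: int | None):
    pos = relwarps.eigenvalues > 0
    scores = relwarps.scores[:, pos]
    lam = relwarps.eigenvalues[pos]
    if n_rws is not None:
        scores, lam = scores[:, :n_rws], lam[:n_rws]
    return scores, lam / lam.sum()


def mu_significance(
    relwarps: RelativeWarps,
    labels: np.ndarray,
    n_resamples: int = 1000,
    mode: str = "bootstrap_labels",
    seed: int | np.random.Generator = 0,
    n_rws: int | None = None,
    range_rule: str = "union_extended",
    grid_points: int = 512,
    _chunk: int = 200,
) -> MUResult:
    """Observed MU plus a resampling p-value.

    ``bootstrap_labels`` draws specimens with replacement into groups of the
    original sizes; ``permute_labels`` shuffles labels without replacement.
    p = (#null ≥ observed + 1) / (n_resamples + 1); bandwidths are re-fitted
    for every resample.  Identical seeds give identical results.
    """
    if n_resamples < 99:
        logger.warning("n_resamples=%d gives a coarse p-value granularity", n_resamples)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask_a, mask_b, _ = _two_level_masks(labels)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    scores, weights = _scores_and_weights(relwarps, n_rws)
    n, m = scores.shape
    obs_u = np.empty(m)
    for j in range(m):
        obs_u[j] = 1.0 - rw_overlap(
            scores[mask_a, j], scores[mask_b, j], range_rule=range_rule, grid_points=grid_points
        )
    observed = float(np.clip(weights @ obs_u, 0.0, 1.0))

    null = np.empty(n_resamples)
    done = 0
    while done < n_resamples:
        r = min(_chunk, n_resamples - done)
        if mode == "bootstrap_labels":
            ia = rng.integers(0, n, size=(r, na))
            ib = rng.integers(0, n, size=(r, nb))
        elif mode == "permute_labels":
            perms = np.argsort(rng.random((r, n)), axis=1)
            ia, ib = perms[:, :na], perms[:, na : na + nb]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        acc = np.zeros(r)
        for j in range(m):
            col = scores[:, j]
            acc += weights[j] * (
                1.0
                - _overlap_batch(
                    col[ia], col[ib], range_rule=range_rule, grid_points=grid_points
                )
            )
        null[done : done + r] = np.clip(acc, 0.0, 1.0)
        done += r

    p = (np.count_nonzero(null >= observed) + 1) / (n_resamples + 1)
    qs = np.quantile(null, [0.5, 0.95, 0.99])
    return MUResult(
        rw_uniqueness=obs_u,
        weights=weights,
        overall_mu=observed,
        group_sizes=(na, nb),
        p_value=float(p),
        n_resamples=n_resamples,
        null_mean=float(null.mean()),
        null_quantiles={"q50": float(qs[0]), "q95": float(qs[1]), "q99": float(qs[2])},
    )


def pairwise_mu(
    relwarps: RelativeWarps,
    labels: np.ndarray,
    min_n: int = 3,
    n_rws: int | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, float]:
    """Symmetric matrix of overall MUs between all level pairs of a factor.

    Levels with fewer than ``min_n`` specimens are dropped with a warning;
    returns the matrix (diagonal 0) and the mean over unordered pairs.
    """
    labels = np.asarray(labels)
    levels = [l for l in dict.fromkeys(labels)]
    kept = []
    for lev in levels:
        if (labels == lev).sum() >= min_n:
            kept.append(lev)
        else:
            logger.warning("level %r has n < %d: dropped from pairwise MU", lev, min_n)
    if len(kept) < 2:
        raise ValueError("need >= 2 usable levels")
    mat = pd.DataFrame(0.0, index=kept, columns=kept)
    vals = []
    for a, b in combinations(kept, 2):
        sub = np.isin(labels, [a, b])
        sub_rw = RelativeWarps(
            scores=relwarps.scores[sub],
            eigenvalues=relwarps.eigenvalues,
            percent_variance=relwarps.percent_variance,
            loadings=relwarps.loadings,
            mean=relwarps.mean,
        )
        res = overall_mu(sub_rw, labels[sub], n_rws=n_rws, **kwargs)
        mat.loc[a, b] = mat.loc[b, a] = res.overall_mu
        vals.append(res.overall_mu)
    return mat, float(np.mean(vals))


def _per_rw_factor_mu(
    scores: np.ndarray, labels: np.ndarray, j: int, min_n: int = 3, **kwargs
) -> float:
    """Uniqueness along RW j for one factor: pairwise mean for >2 levels."""
    labels = np.asarray(labels)
    levels = [l for l in dict.fromkeys(labels) if (labels == l).sum() >= min_n]
    if len(levels) < 2:
        raise ValueError("need >= 2 usable levels")
    vals = []
    for a, b in combinations(levels, 2):
        vals.append(
            1.0 - rw_overlap(scores[labels == a, j], scores[labels == b, j], **kwargs)
        )
    return float(np.mean(vals))


@dataclass
class DominanceTable:
    table: pd.DataFrame  # rows RW1…, columns: percent_variance, one per factor, dominant
    rw_dom: pd.Series  # dominated-RW count per factor
    overall: pd.Series  # overall (weighted) MU per factor

    @property
    def ranking(self) -> list[str]:
        return list(self.overall.sort_values(ascending=False).index)


def dominance_table(
    relwarps: RelativeWarps,
    factors: dict[str, np.ndarray],
    n_rws: int | None = None,
    min_n: int = 3,
    **kwargs,
) -> DominanceTable:
    """Per-RW MU of every factor, the per-RW dominant factor and RW_DOM counts.

    Multi-level factors enter as the unweighted mean of their pairwise MUs;
    the overall column weights per-RW values by eigenvalue proportions.
    """
    scores, weights = _scores_and_weights(relwarps, n_rws)
    m = scores.shape[1]
    names = list(factors)
    rows = []
    for j in range(m):
        row = {"percent_variance": relwarps.percent_variance[j]}
        for name in names:
            row[name] = _per_rw_factor_mu(scores, factors[name], j, min_n=min_n, **kwargs)
        rows.append(row)
    table = pd.DataFrame(rows, index=[f"RW{j + 1}" for j in range(m)])
    table["dominant"] = table[names].idxmax(axis=1)
    rw_dom = table["dominant"].value_counts().reindex(names, fill_value=0)
    overall = pd.Series(
        {name: float(np.clip(weights @ table[name].to_numpy(), 0, 1)) for name in names}
    )
    return DominanceTable(table=table, rw_dom=rw_dom, overall=overall)
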