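"""Unsupervised model-based clustering of relative-warp scores.

A diagonal-covariance Gaussian mixture fitted by EM, with per-variable
variance floors standing in for the fixed per-variable error terms of the
classic Autoclass formulation, and an approximate log marginal likelihood
(Cheeseman–Stutz) for choosing the number of clusters.  Restarted from many
random responsibilities; deterministic under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureModel:
    n_clusters: int
    weights: np.ndarray  # (K,) simplex
    means: np.ndarray  # (K, m)
    variances: np.ndarray  # (K, m), >= floor
    log_likelihood: float
    log_score: float  # approximate log marginal likelihood
    posteriors: np.ndarray  # (n, K), rows sum to 1
    error_floor: np.ndarray  # (m,) variance floors
    converged: bool
    em_iterations: int
    seed: int | None = None
    restarts: int = 0
    score_method: str = "cheeseman_stutz"

    def hard_assignments(self) -> np.ndarray:
        return self.posteriors.argmax(axis=1)


def _log_gauss_diag(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, K) log density of each point under each diagonal Gaussian."""
    d2 = (x[:, None, :] - means[None, :, :]) ** 2 / variances[None, :, :]
    return -0.5 * (d2 + np.log(variances)[None, :, :] + LOG2PI).sum(axis=2)


def _em_once(
    x: np.ndarray,
    k: int,
    floor: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    tol_streak: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    n, m = x.shape
    # random fractional responsibilities as the starting point
    resp = rng.dirichlet(np.ones(k), size=n)
    weights = np.full(k, 1.0 / k)
    means = x[rng.choice(n, size=k, replace=False)]
    variances = np.maximum(x.var(axis=0)[None, :].repeat(k, axis=0), floor)
    prev_ll = -np.inf
    prev_params = None
    streak = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nk = resp.sum(axis=0) + 1e-10
        weights = nk / nk.sum()
        means = (resp.T @ x) / nk[:, None]
        diff2 = (x[:, None, :] - means[None, :, :]) ** 2
        variances = np.einsum("nk,nkm->km", resp, diff2) / nk[:, None]
        variances = np.maximum(variances, floor[None, :])
        logp = _log_gauss_diag(x, means, variances) + np.log(weights)[None, :]
        ll = float(logsumexp(logp, axis=1).sum())
        if ll + 1e-9 < prev_ll:
            logger.debug("EM objective decreased by %.3g (floor active)", prev_ll - ll)
        resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        params = np.concatenate([weights, means.ravel(), np.sqrt(variances).ravel()])
        if prev_params is not None:
            streak = streak + 1 if np.abs(params - prev_params).max() < tol else 0
            if streak >= tol_streak:
                converged = True
                prev_ll = ll
                break
        prev_params = params
        prev_ll = ll
    return weights, means, variances, resp, prev_ll, converged, it


def _cheeseman_stutz_score(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    resp: np.ndarray,
    log_likelihood: float,
) -> float:
    """Cheeseman–Stutz approximation to log p(data | K).

    CS = log p(X|θ̂) + log m(X, ẑ) − log p(X, ẑ|θ̂), with fractional
    assignments ẑ and a conjugate complete-data marginal (symmetric
    Dirichlet(1) on weights, normal–inverse-gamma per cluster and variable
    anchored at the overall data moments).
    """
    n, m = x.shape
    k = weights.size
    nk = resp.sum(axis=0)
    # log p(X, ẑ | θ̂): responsibility-weighted complete-data log likelihood
    logp = _log_gauss_diag(x, means, variances) + np.log(np.maximum(weights, 1e-300))
    log_complete_at_theta = float((resp * logp).sum())

    # Dirichlet-multinomial marginal over assignments (fractional counts)
    alpha = 1.0
    log_m = (
        gammaln(k * alpha)
        - gammaln(k * alpha + n)
        + (gammaln(alpha + nk) - gammaln(alpha)).sum()
    )
    # NIG marginal per cluster/variable with weighted sufficient statistics
    # unit-information conjugate prior anchored at the overall data moments:
    # one pseudo-observation per cluster/variable keeps the Occam factor
    # near 0.5·log(n_k) per parameter instead of over-penalising means
    mu0 = x.mean(axis=0)
    kappa0 = 1.0
    nu0 = 1.0
    s0 = np.maximum(x.var(axis=0), 1e-12)  # prior scale anchored at data variance
    for j in range(k):
        w = resp[:, j]
        nj = nk[j]
        if nj <= 1e-8:
            continue
        xbar = (w @ x) / nj
        ss = w @ (x - xbar) ** 2  # (m,)
        kappa_n = kappa0 + nj
        nu_n = nu0 + nj
        a0, an = nu0 / 2.0, nu_n / 2.0
        b0 = nu0 * s0 / 2.0
        bn = b0 + ss / 2.0 + kappa0 * nj * (xbar - mu0) ** 2 / (2.0 * kappa_n)
        log_m += float(
            (
                -0.5 * nj * LOG2PI
                + 0.5 * (np.log(kappa0) - np.log(kappa_n))
                + a0 * np.log(b0)
                - an * np.log(bn)
                + gammaln(an)
                - gammaln(a0)
            ).sum()
        )
    return float(log_likelihood + log_m - log_complete_at_theta)


def fit_mixture(
    scores: np.ndarray,
    k: int,
    error_floor: np.ndarray | float | None = None,
    seed: int = 0,
    restarts: int = 50,
    max_iter: int = 500,
    tol: float = 2.5e-3,
    tol_streak: int = 10,
    score_method: str = "cheeseman_stutz",
) -> MixtureModel:
    """EM fit of a K-cluster diagonal Gaussian mixture with variance floors.

    ``error_floor`` gives per-variable variance floors; the default is
    1e-3 × the per-variable standard deviation, computed from all
    specimens.  The best of ``restarts`` random initialisations by
    in-sample log likelihood is kept; convergence requires every parameter
    to move < ``tol`` over ``tol_streak`` consecutive iterations.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("scores must be 2-D (n, m)")
    n, m = x.shape
    if k >= n:
        raise ValueError(f"K={k} >= n={n}")
    if k < 1:
        raise ValueError("K must be >= 1")
    if error_floor is None:
        floor = 1e-3 * x.std(axis=0, ddof=1)
    else:
        floor = np.broadcast_to(np.asarray(error_floor, dtype=float), (m,)).copy()
    floor = np.maximum(floor, 1e-12)

    if k == 1:
        weights = np.ones(1)
        means = x.mean(axis=0)[None, :]
        variances = np.maximum(x.var(axis=0)[None, :], floor[None, :])
        resp = np.ones((n, 1))
        ll = float(_log_gauss_diag(x, means, variances).sum())
        best = (weights, means, variances, resp, ll, True, 0)
    else:
        root = np.random.default_rng(seed)
        best = None
        for r in range(restarts):
            rng = np.random.default_rng(root.integers(0, 2**31 - 1))
            out = _em_once(x, k, floor, rng, max_iter, tol, tol_streak)
            if best is None or out[4] > best[4]:
                best = out
        if not best[5]:
            logger.warning("EM did not converge for K=%d in %d iterations", k, max_iter)
    weights, means, variances, resp, ll, converged, it = best
    if score_method == "cheeseman_stutz":
        score = _cheeseman_stutz_score(x, weights, means, variances, resp, ll)
    elif score_method == "bic":
        n_params = (k - 1) + 2 * k * m
        score = ll - 0.5 * n_params * np.log(n)
    else:
        raise ValueError(f"unknown score_method {score_method!r}")
    return MixtureModel(
        n_clusters=k,
        weights=weights,
        means=means,
        variances=variances,
        log_likelihood=ll,
        log_score=score,
        posteriors=resp,
        error_floor=floor,
        converged=converged,
        em_iterations=it,
        seed=seed,
        restarts=restarts,
        score_method=score_method,
    )


@dataclass
class ClusterSelection:
    best: MixtureModel
    models: dict[int, MixtureModel]
    score_table: pd.DataFrame  # K, log_likelihood, log_score, converged
    ratio_vs_runner_up: float  # exp(best − runner-up log score)

    @property
    def best_k(self) -> int:
        return self.best.n_clusters


def select_clusters(
    scores: np.ndarray,
    k_max: int = 6,
    seed: int = 0,
    restarts: int = 50,
    score_method: str = "cheeseman_stutz",
    **kwargs,
) -> ClusterSelection:
    """Fit K = 1…k_max mixtures and keep the best by log marginal score.

    The probability ratio against the runner-up is exp(Δ log score), the
    analogue of "x times more probable than the next best classification".
    """
    x = np.asarray(scores, dtype=float)
    if k_max >= x.shape[0]:
        raise ValueError("k_max must be < n")
    models = {}
    for k in range(1, k_max + 1):
        models[k] = fit_mixture(
            x, k, seed=seed + k, restarts=restarts, score_method=score_method, **kwargs
        )
    table = pd.DataFrame(
        {
            "K": list(models),
            "log_likelihood": [m.log_likelihood for m in models.values()],
            "log_score": [m.log_score for m in models.values()],
            "converged": [m.converged for m in models.values()],
        }
    ).set_index("K")
    ranked = table["log_score"].sort_values(ascending=False)
    best = models[int(ranked.index[0])]
    ratio = float(np.exp(ranked.iloc[0] - ranked.iloc[1])) if len(ranked) > 1 else np.inf
    return ClusterSelection(best=best, models=models, score_table=table, ratio_vs_runner_up=ratio)


def assignment_plot_data(
    model: MixtureModel,
    specimen_ids: list[str] | np.ndarray,
    order_by: np.ndarray | None = None,
) -> pd.DataFrame:
    """Stacked-posterior rows for assignment plots, one row per specimen.

    Rows are ordered by the grouping factor, then by descending maximum
    posterior, with specimen id as the deterministic tie-break.
    """
    ids = np.asarray(specimen_ids, dtype=object)
    k = model.n_clusters
    df = pd.DataFrame(
        model.posteriors, columns=[f"cluster_{j + 1}" for j in range(k)]
    )
    df.insert(0, "specimen_id", ids)
    df["max_posterior"] = model.posteriors.max(axis=1)
    df["assigned"] = model.hard_assignments() + 1
    if order_by is not None:
        df["group"] = np.asarray(order_by, dtype=object)
        df = df.sort_values(
            ["group", "max_posterior", "specimen_id"], ascending=[True, False, True]
        )
    else:
        df = df.sort_values(["max_posterior", "specimen_id"], ascending=[False, True])
    return df.reset_index(drop=True)
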