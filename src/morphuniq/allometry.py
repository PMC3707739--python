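"""Centroid-size analysis and multivariate allometric size correction.

Sizes may be log-transformed to normality before use (Shapiro–Wilk decision
rule).  Shape variables are regressed on the size covariate with a MANCOVA
pre-test of the sex × size interaction: when the interaction does not
explain significant shape variation a single pooled regression serves both
sexes and its residuals replace the shape variables downstream; otherwise
residuals are taken within sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def choose_size_transform(sizes: np.ndarray, alpha: float = 0.05) -> str:
    """Pick ``"identity"`` or ``"log"`` by Shapiro–Wilk normality at alpha.

    Log is chosen only when the raw sizes fail normality and their natural
    logs pass; if both fail, identity is kept with a warning.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < 8:
        raise ValueError("need n >= 8 to judge normality")
    if np.ptp(sizes) == 0:
        raise ValueError("constant sizes: zero variance")
    p_raw = stats.shapiro(sizes).pvalue
    if p_raw >= alpha:
        return "identity"
    if np.any(sizes <= 0):
        raise ValueError("non-positive sizes cannot be log-transformed")
    p_log = stats.shapiro(np.log(sizes)).pvalue
    if p_log >= alpha:
        return "log"
    logger.warning(
        "neither raw (p=%.3g) nor log (p=%.3g) sizes look normal; keeping identity",
        p_raw,
        p_log,
    )
    return "identity"


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]


def welch_t_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> WelchResult:
    """Welch unequal-variance t from summary statistics (Welch–Satterthwaite df)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    se = np.sqrt(va + vb)
    if se == 0:
        raise ValueError("both groups have zero variance")
    t = (mean_a - mean_b) / se
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), (mean_a, mean_b), (sd_a, sd_b), (n_a, n_b))


def welch_t_sizes(sizes: np.ndarray, groups: np.ndarray) -> WelchResult:
    """Welch t test of sizes between the two levels of ``groups``.

    Levels are ordered by first appearance; the t statistic is
    (mean₁ − mean₂) for that ordering.
    """
    sizes = np.asarray(sizes, dtype=float)
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    a = sizes[groups == levels[0]]
    b = sizes[groups == levels[1]]
    return welch_t_from_stats(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


@dataclass
class SizeCorrectionResult:
    transform: str
    interaction_p: float
    pooled: bool
    slopes: np.ndarray  # (m,) pooled slope vector (or mean of within-sex slopes)
    residual_shape: np.ndarray  # (n, m)
    percent_size_variance: float
    covariate: np.ndarray  # (n,) the (possibly log) size actually regressed on


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and coefficients of multivariate OLS of y on design x."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef, coef


def size_correct(
    shape_scores: np.ndarray,
    sizes: np.ndarray,
    sex: np.ndarray,
    alpha: float = 0.05,
    transform: str | None = None,
    method: str = "common_within",
) -> SizeCorrectionResult:
    """Allometric MANCOVA residuals of shape variables on (possibly log) size.

    Fits shape ~ sex + size + sex×size (sex effect-coded), tests the
    interaction with Wilks' Λ.  When the interaction is non-significant a
    single common slope serves both sexes; otherwise sex-specific slopes are
    used (logged).  Either way only the size term is subtracted, so group
    (sex) shape differences survive into the residuals, which is what makes
    them usable by the downstream group analyses.

    ``method`` picks how the common slope is estimated:

    - ``"common_within"`` (default): slope from the MANCOVA with sex in the
      model — the pooled within-group slope.  Size and sex are correlated,
      so this is the estimate that does not confound the sex mean shift
      with allometry.
    - ``"pooled_simple"``: slope from a size-only regression ignoring sex;
      residuals are then exactly orthogonal to the size covariate, at the
      price of absorbing the size-predictable part of any group difference.

    ``transform=None`` applies the Shapiro–Wilk decision rule;
    ``"identity"``/``"log"`` force a choice.
    """
    from .linmodels import wilks_model_comparison

    y = np.asarray(shape_scores, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    sex = np.asarray(sex)
    n, m = y.shape
    if n <= m + 3:
        raise ValueError(f"need n > m + 3 (n={n}, m={m})")
    if transform is None:
        transform = choose_size_transform(sizes, alpha=alpha)
    cov = np.log(sizes) if transform == "log" else sizes.copy()

    levels = list(dict.fromkeys(sex))
    if len(levels) != 2:
        raise ValueError("sex must have exactly 2 levels")
    s = np.where(sex == levels[0], 1.0, -1.0)
    c = cov - cov.mean()
    full = np.column_stack([np.ones(n), s, c, s * c])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("rank-deficient design (sex confounded with size?)")
    reduced = full[:, :3]
    inter = wilks_model_comparison(y, full, reduced)

    if inter.p > alpha:
        if method == "common_within":
            _, coef = _ols_residuals(y, reduced)  # [1, sex, size]
            slopes = coef[2]
        elif method == "pooled_simple":
            _, coef = _ols_residuals(y, np.column_stack([np.ones(n), c]))
            slopes = coef[1]
        else:
            raise ValueError(f"unknown method {method!r}")
        resid = y - np.outer(c, slopes)
        resid = resid - resid.mean(axis=0)
        pooled = True
    else:
        logger.info(
            "sex × size interaction significant (p=%.4f): sex-specific slopes", inter.p
        )
        resid = y.copy()
        slope_list = []
        for lev in levels:
            mask = sex == lev
            cg = c[mask] - c[mask].mean()
            xg = np.column_stack([np.ones(int(mask.sum())), cg])
            _, coef = _ols_residuals(y[mask], xg)
            resid[mask] = y[mask] - np.outer(cg, coef[1])
            slope_list.append(coef[1])
        resid = resid - resid.mean(axis=0)
        slopes = np.mean(slope_list, axis=0)
        pooled = False

    total = ((y - y.mean(0)) ** 2).sum()
    resid_ss = ((resid - resid.mean(0)) ** 2).sum()
    pct = 100.0 * max(0.0, min(1.0, 1.0 - resid_ss / max(total, 1e-300)))
    return SizeCorrectionResult(
        transform=transform,
        interaction_p=float(inter.p),
        pooled=pooled,
        slopes=np.asarray(slopes),
        residual_shape=resid,
        percent_size_variance=pct,
        covariate=cov,
    )
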