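"""Multivariate linear-model inference for shape variables.

Type-III MANOVA with Wilks' Λ via explicit SSCP model comparison on
effect-coded (sum-to-zero) designs, Rao's F approximation, multivariate
partial η² = 1 − Λ^(1/s) and observed power from the noncentral F; nested
designs (population within host); a bootstrap trajectory-angle comparison
between groups' leading principal axes; and the gene-flow influence index
with its shape-dispersion regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design coding
# ---------------------------------------------------------------------------

def effect_code(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero coding: L levels → L−1 columns, last level coded −1."""
    labels = np.asarray(labels)
    levels = sorted(dict.fromkeys(labels), key=str)
    l = len(levels)
    if l < 2:
        raise ValueError("factor needs >= 2 levels")
    cols = np.zeros((labels.size, l - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols, levels


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("ni,nj->nij", a, b).reshape(a.shape[0], -1)


@dataclass
class ManovaResult:
    effect: str
    wilks_lambda: float
    f: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float  # fraction, not percent
    observed_power: float
    df_h: int  # hypothesis df (columns tested)
    df_e: int  # error df (n − rank of full design)
    defined: bool = True


def _wilks_stats(
    e: np.ndarray, h: np.ndarray, df_h: int, df_e: int, m: int, alpha: float = 0.05
) -> tuple[float, float, float, float, float, float, float]:
    """Wilks Λ with Rao's F, p, partial η² and observed power."""
    lam = float(np.linalg.det(e) / np.linalg.det(e + h))
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    p_, q = m, df_h
    if p_**2 + q**2 - 5 > 0:
        s = np.sqrt((p_**2 * q**2 - 4) / (p_**2 + q**2 - 5))
    else:
        s = 1.0
    df1 = p_ * q
    df2 = s * (df_e - (p_ - q + 1) / 2.0) - (p_ * q - 2) / 2.0
    lam_s = lam ** (1.0 / s)
    f = (1.0 - lam_s) / lam_s * df2 / df1
    pval = float(stats.f.sf(f, df1, df2)) if df2 > 0 else np.nan
    eta = 1.0 - lam ** (1.0 / min(p_, q))
    # observed power: noncentral F with λ_nc = F · df1 (package convention)
    if df2 > 0:
        crit = stats.f.ppf(1 - alpha, df1, df2)
        power = float(stats.ncf.sf(crit, df1, df2, f * df1))
    else:
        power = np.nan
    return lam, float(f), float(df1), float(df2), pval, float(eta), power


@dataclass
class WilksComparison:
    wilks_lambda: float
    f: float
    df1: float
    df2: float
    p: float


def wilks_model_comparison(
    y: np.ndarray, full_design: np.ndarray, reduced_design: np.ndarray
) -> WilksComparison:
    """Wilks test of the columns present in full but not in reduced."""
    y = np.asarray(y, dtype=float)
    e_full, rank_full = _resid_sscp(y, full_design)
    e_red, _ = _resid_sscp(y, reduced_design)
    h = e_red - e_full
    df_h = rank_full - np.linalg.matrix_rank(reduced_design)
    df_e = y.shape[0] - rank_full
    lam, f, df1, df2, p, _, _ = _wilks_stats(e_full, h, df_h, df_e, y.shape[1])
    return WilksComparison(lam, f, df1, df2, p)


def _resid_sscp(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, int]:
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ coef
    return r.T @ r, rank


def manova(
    responses: np.ndarray,
    factors: dict[str, np.ndarray],
    interactions: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> list[ManovaResult]:
    """Type-III MANOVA of all factors (and listed two-way interactions).

    Every effect is tested by dropping its effect-coded columns from the
    full model while keeping all other terms — the type-III comparison that
    accounts for unbalanced cell counts.  Λ = |E| / |E + H| with H the SSCP
    difference between reduced- and full-model residuals.
    """
    y = np.asarray(responses, dtype=float)
    n, m = y.shape
    blocks: dict[str, np.ndarray] = {}
    for name, labels in factors.items():
        blocks[name], _ = effect_code(np.asarray(labels))
    for a, b in interactions or []:
        blocks[f"{a}:{b}"] = _interaction(blocks[a], blocks[b])
    names = list(blocks)
    full = np.column_stack([np.ones(n)] + [blocks[nm] for nm in names])
    rank_full = np.linalg.matrix_rank(full)
    if rank_full < full.shape[1]:
        aliased = _find_aliased(blocks, n)
        raise ValueError(f"rank-deficient design; aliased effects: {aliased}")
    df_e = n - rank_full
    if df_e <= m:
        raise ValueError(f"too few error df (df_e={df_e} <= m={m}): singular E")
    e_full, _ = _resid_sscp(y, full)
    results = []
    for nm in names:
        reduced = np.column_stack(
            [np.ones(n)] + [blocks[o] for o in names if o != nm]
        )
        e_red, _ = _resid_sscp(y, reduced)
        h = e_red - e_full
        df_h = blocks[nm].shape[1]
        lam, f, df1, df2, p, eta, power = _wilks_stats(e_full, h, df_h, df_e, m, alpha)
        results.append(
            ManovaResult(nm, lam, f, df1, df2, p, eta, power, df_h, df_e)
        )
    return results


def _find_aliased(blocks: dict[str, np.ndarray], n: int) -> list[str]:
    aliased = []
    acc = np.ones((n, 1))
    for nm, b in blocks.items():
        cand = np.column_stack([acc, b])
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            aliased.append(nm)
        else:
            acc = cand
    return aliased


def manova_nested(
    responses: np.ndarray,
    outer: np.ndarray,
    inner: np.ndarray,
    outer_name: str = "host",
    inner_name: str = "population",
    alpha: float = 0.05,
) -> list[ManovaResult]:
    """Nested MANOVA: outer factor plus inner factor nested within outer.

    Each inner level must map to exactly one outer level.  The nested term
    gets Σ(levels − 1) effect-coded columns, one block per outer level; a
    block with zero columns (one inner level per outer level everywhere)
    makes the nested effect undefined and is reported with a flag.
    """
    y = np.asarray(responses, dtype=float)
    outer = np.asarray(outer)
    inner = np.asarray(inner)
    n, m = y.shape
    mapping: dict[object, set] = {}
    for i_lev, o_lev in zip(inner, outer):
        mapping.setdefault(i_lev, set()).add(o_lev)
    bad = [i for i, o in mapping.items() if len(o) > 1]
    if bad:
        raise ValueError(f"inner level(s) span multiple outer levels: {bad}")

    outer_cols, outer_levels = effect_code(outer)
    nested_blocks = []
    for o_lev in outer_levels:
        mask = outer == o_lev
        levs = sorted(dict.fromkeys(inner[mask]), key=str)
        if len(levs) < 2:
            continue
        sub, _ = effect_code(inner[mask])
        block = np.zeros((n, sub.shape[1]))
        block[mask] = sub
        nested_blocks.append(block)
    results = []
    if not nested_blocks:
        full = np.column_stack([np.ones(n), outer_cols])
        e_full, rank_full = _resid_sscp(y, full)
        df_e = n - rank_full
        e_red, _ = _resid_sscp(y, np.ones((n, 1)))
        lam, f, df1, df2, p, eta, power = _wilks_stats(
            e_full, e_red - e_full, outer_cols.shape[1], df_e, m, alpha
        )
        results.append(
            ManovaResult(outer_name, lam, f, df1, df2, p, eta, power, outer_cols.shape[1], df_e)
        )
        results.append(
            ManovaResult(
                f"{inner_name}({outer_name})",
                np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                0, 0, defined=False,
            )
        )
        logger.warning("nested effect has 0 df: one inner level per outer level")
        return results
    nested = np.column_stack(nested_blocks)
    full = np.column_stack([np.ones(n), outer_cols, nested])
    rank_full = np.linalg.matrix_rank(full)
    if rank_full < full.shape[1]:
        raise ValueError("rank-deficient nested design")
    df_e = n - rank_full
    e_full, _ = _resid_sscp(y, full)
    for nm, drop, df_h in (
        (outer_name, outer_cols, outer_cols.shape[1]),
        (f"{inner_name}({outer_name})", nested, nested.shape[1]),
    ):
        keep = [c for c in (outer_cols, nested) if c is not drop]
        reduced = np.column_stack([np.ones(n)] + keep)
        e_red, _ = _resid_sscp(y, reduced)
        lam, f, df1, df2, p, eta, power = _wilks_stats(
            e_full, e_red - e_full, df_h, df_e, m, alpha
        )
        results.append(ManovaResult(nm, lam, f, df1, df2, p, eta, power, df_h, df_e))
    return results


def manova_table(results: list[ManovaResult]) -> pd.DataFrame:
    """Report-style table: Λ, F, dfs, P, η² in percent, observed power."""
    return pd.DataFrame(
        {
            "effect": [r.effect for r in results],
            "wilks_lambda": [r.wilks_lambda for r in results],
            "F": [r.f for r in results],
            "df1": [r.df1 for r in results],
            "df2": [r.df2 for r in results],
            "P": [r.p for r in results],
            "partial_eta_sq_pct": [100.0 * r.partial_eta_sq for r in results],
            "observed_power": [r.observed_power for r in results],
        }
    ).set_index("effect")


# ---------------------------------------------------------------------------
# trajectory angle between groups
# ---------------------------------------------------------------------------

def _leading_axis(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / max(x.shape[0] - 1, 1)
    if not np.isfinite(cov).all() or np.allclose(cov, 0):
        raise ValueError("degenerate covariance")
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, -1]


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(min(1.0, c))))


@dataclass
class TrajectoryAngleResult:
    angle_deg: float  # between-group angle of leading axes, in [0, 90]
    p_value: float  # fraction of within-group wander angles >= observed
    n_boot: int
    null_angles: np.ndarray


def trajectory_angle(
    a: np.ndarray, b: np.ndarray, n_boot: int = 999, seed: int = 0
) -> TrajectoryAngleResult:
    """Angle between two groups' leading principal axes with a bootstrap test.

    The null spread is the angle between two *independent* bootstrap
    re-estimates of one group's axis (alternating groups), which carries the
    same two sources of axis error as the observed between-group angle;
    p = (1 + #{null ≥ observed}) / (n_boot + 1).  A small p says the
    between-group angle exceeds what sampling noise produces, i.e. the
    groups do NOT share a trajectory.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    axis_a = _leading_axis(a)
    axis_b = _leading_axis(b)
    observed = _angle_deg(axis_a, axis_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for i in range(n_boot):
        sample = a if i % 2 == 0 else b
        i1 = rng.integers(0, sample.shape[0], size=sample.shape[0])
        i2 = rng.integers(0, sample.shape[0], size=sample.shape[0])
        try:
            null[i] = _angle_deg(_leading_axis(sample[i1]), _leading_axis(sample[i2]))
        except ValueError:
            null[i] = 90.0
    p = (1 + np.count_nonzero(null >= observed)) / (n_boot + 1)
    return TrajectoryAngleResult(observed, float(p), n_boot, null)


# ---------------------------------------------------------------------------
# gene flow: influence index and dispersion regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InfluenceRecord:
    population: str
    prop_focal: float
    prop_adjacent: float
    distance: float
    influence: float


def influence_index(
    records: list[tuple[str, float, float, float]]
) -> list[InfluenceRecord]:
    """Gene-flow proxy: (prop_focal + prop_adjacent) / distance per population."""
    out = []
    for pop, pf, pa, dist in records:
        if not (0 <= pf <= 1 and 0 <= pa <= 1):
            raise ValueError(f"{pop}: proportions must be in [0, 1]")
        if dist <= 0:
            raise ValueError(f"{pop}: distance must be > 0")
        out.append(InfluenceRecord(pop, pf, pa, dist, (pf + pa) / dist))
    return out


@dataclass
class DispersionRegression:
    sem_table: pd.DataFrame  # per population: SEM of RW1..RW3 + mean_sem, influence
    per_rw: pd.DataFrame  # slope, intercept, r2, p per RW response
    mean_sem_fit: dict  # slope, intercept, r2, p for the mean-SEM response
    flagged: list[str]  # populations with zero dispersion


def dispersion_vs_influence(
    rw_scores: np.ndarray,
    populations: np.ndarray,
    influence: dict[str, float],
    n_rws: int = 3,
) -> DispersionRegression:
    """Regress per-population shape dispersion (SEM of leading RW scores)
    on the gene-flow influence index, per RW and for the mean SEM."""
    scores = np.asarray(rw_scores, dtype=float)[:, :n_rws]
    populations = np.asarray(populations)
    pops = [p for p in dict.fromkeys(populations) if p in influence]
    if len(pops) < 3:
        raise ValueError("need >= 3 populations with influence values")
    rows, flagged = [], []
    for pop in pops:
        sub = scores[populations == pop]
        if sub.shape[0] < 2:
            raise ValueError(f"population {pop}: need n >= 2 for a SEM")
        sem = sub.std(axis=0, ddof=1) / np.sqrt(sub.shape[0])
        if np.any(sem == 0):
            flagged.append(pop)
            logger.warning("population %s has zero dispersion on some RW", pop)
        rows.append(
            {"population": pop, **{f"sem_rw{j + 1}": sem[j] for j in range(n_rws)},
             "mean_sem": sem.mean(), "influence": influence[pop]}
        )
    table = pd.DataFrame(rows).set_index("population")

    def fit(yv: np.ndarray) -> dict:
        res = stats.linregress(table["influence"].to_numpy(), yv)
        return {
            "slope": res.slope,
            "intercept": res.intercept,
            "r2": res.rvalue**2,
            "p": res.pvalue,
        }

    per_rw = pd.DataFrame(
        {f"RW{j + 1}": fit(table[f"sem_rw{j + 1}"].to_numpy()) for j in range(n_rws)}
    ).T
    return DispersionRegression(
        sem_table=table,
        per_rw=per_rw,
        mean_sem_fit=fit(table["mean_sem"].to_numpy()),
        flagged=flagged,
    )
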