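"""End-to-end orchestration: landmarks → GPA → shape variables → size
correction → relative warps → uniqueness / clustering / MANOVA / gene flow.

Every stage is a pure function of the upstream artifacts plus the run
configuration; all randomness flows from one root seed through named
substreams, so a config + seed pair reproduces the run bit for bit.  Stage
outputs are written as CSV/JSON under the output directory together with a
manifest of SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, linmodels, mixtures, uniqueness, warps
from .io import LandmarkDataset, read_csv, read_factors, read_tps, validate_dataset, write_csv
from .procrustes import gpa_align
from .simulate import INFLUENCE

logger = logging.getLogger(__name__)

STAGES = ("validate", "gpa", "warps", "correct", "relwarps", "mu", "cluster", "manova", "geneflow")


@dataclass
class RunConfig:
    landmarks: str | None = None  # .tps or .csv path; None when a dataset is passed directly
    factors: str | None = None
    out_dir: str = "results/run"
    view: str = "lingual"
    transform: str | None = "log"  # None → Shapiro–Wilk decision
    correction_method: str = "common_within"
    mu_resamples: int = 1000
    mu_range_rule: str = "union_extended"
    mu_null_mode: str = "bootstrap_labels"
    cluster_kmax: int = 3
    cluster_restarts: int = 12
    cluster_score: str = "cheeseman_stutz"
    influence: dict[str, float] = field(default_factory=lambda: dict(INFLUENCE))
    males_only: bool = False  # sex-removal mode: wild males, populations with >= min_pop
    min_pop: int = 9
    seed: int = 0


def _substream(seed: int, stage: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.sha256(f"{seed}:{stage}".encode()).digest()[:4], "big")
    return np.random.default_rng(h % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_dataset(config: RunConfig) -> LandmarkDataset:
    if config.landmarks is None:
        raise FileNotFoundError("no landmark path configured")
    path = Path(config.landmarks)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    if path.suffix.lower() == ".tps":
        ds = read_tps(path, view=config.view)
        if config.factors:
            fpath = Path(config.factors)
            if not fpath.exists():
                raise FileNotFoundError(f"factor file not found: {fpath}")
            ds = LandmarkDataset(ds.configurations, read_factors(fpath))
    else:
        ds = read_csv(path, view=config.view)
    return ds


def sex_removal_filter(dataset: LandmarkDataset, min_pop: int = 9) -> LandmarkDataset:
    """Wild (field-collected) males from populations with >= min_pop of them.

    The sex-removal workflow then rebuilds consensus and shape variables
    from scratch on this subset.
    """
    sex = dataset.factor("sex")
    rearing = dataset.factor("rearing")
    pops = dataset.factor("population")
    ids = np.array(dataset.specimen_ids)
    wild_male = (sex == "M") & (rearing == "FLD")
    counts = pd.Series(pops[wild_male]).value_counts()
    good_pops = set(counts[counts >= min_pop].index)
    keep = ids[wild_male & np.isin(pops, list(good_pops))]
    return dataset.subset(keep)


def run_pipeline(
    config: RunConfig, dataset: LandmarkDataset | None = None
) -> dict:
    """Run the full analysis; returns the in-memory report bundle.

    Artifacts (CSV/JSON tables mirroring the study's report layout) are
    written under ``config.out_dir`` with a checksum manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": asdict(config)}
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2))

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("validate")
        if dataset is None:
            dataset = load_dataset(config)
        report, dataset = validate_dataset(dataset, strict=True)
        report.to_json(out / "validation.json")
        bundle["validation"] = report.to_dict()
        if config.males_only:
            dataset = sex_removal_filter(dataset, config.min_pop)
            bundle["n_after_sex_removal"] = len(dataset)
    except Exception as exc:
        raise RuntimeError(f"stage 'validate' failed: {exc}") from exc

    try:
        stage("gpa")
        gpa = gpa_align(dataset)
        cons = pd.DataFrame(gpa.consensus, columns=["x", "y"])
        cons.to_csv(out / "consensus.csv", index=False)
        pd.DataFrame(
            {"specimen_id": dataset.specimen_ids, "centroid_size": gpa.centroid_sizes}
        ).to_csv(out / "centroid_sizes.csv", index=False)
        bundle["gpa"] = gpa
    except Exception as exc:
        raise RuntimeError(f"stage 'gpa' failed: {exc}") from exc

    try:
        stage("warps")
        basis = warps.build_shape_basis(gpa.consensus)
        sv = warps.shape_variables(gpa, basis)
        sv_df = pd.DataFrame(sv.scores, columns=basis.variable_names())
        sv_df.insert(0, "specimen_id", dataset.specimen_ids)
        sv_df.to_csv(out / "shape_variables.csv", index=False)
        bundle["shape_variables"] = sv
    except Exception as exc:
        raise RuntimeError(f"stage 'warps' failed: {exc}") from exc

    sexes = dataset.factor("sex")
    try:
        stage("correct")
        if len(set(sexes)) == 2:
            corr = allometry.size_correct(
                sv.scores,
                gpa.centroid_sizes,
                sexes,
                transform=config.transform,
                method=config.correction_method,
            )
            resid = corr.residual_shape
            prov = {
                "transform": corr.transform,
                "interaction_p": corr.interaction_p,
                "pooled": corr.pooled,
                "method": config.correction_method,
                "percent_size_variance": corr.percent_size_variance,
            }
        else:  # single-sex runs still remove allometry
            cov = np.log(gpa.centroid_sizes) if config.transform == "log" else gpa.centroid_sizes
            c = cov - cov.mean()
            x = np.column_stack([np.ones(len(c)), c])
            coef, *_ = np.linalg.lstsq(x, sv.scores, rcond=None)
            resid = sv.scores - np.outer(c, coef[1])
            resid = resid - resid.mean(0)
            prov = {"transform": config.transform, "single_sex": True}
        json.dumps(prov)
        (out / "size_correction.json").write_text(json.dumps(prov, indent=2))
        bundle["size_correction"] = prov
    except Exception as exc:
        raise RuntimeError(f"stage 'correct' failed: {exc}") from exc

    try:
        stage("relwarps")
        rw = warps.relative_warps(resid, specimen_ids=dataset.specimen_ids)
        rw_df = pd.DataFrame(rw.scores, columns=[f"RW{j+1}" for j in range(rw.m)])
        rw_df.insert(0, "specimen_id", dataset.specimen_ids)
        rw_df.to_csv(out / "relative_warps.csv", index=False)
        pd.DataFrame(
            {"eigenvalue": rw.eigenvalues, "percent_variance": rw.percent_variance}
        ).to_csv(out / "rw_variance.csv", index=False)
        bundle["relative_warps"] = rw
    except Exception as exc:
        raise RuntimeError(f"stage 'relwarps' failed: {exc}") from exc

    factors = {}
    for name in ("sex", "host", "population", "rearing"):
        vals = dataset.factor(name)
        if len(set(vals)) >= 2:
            factors[name] = vals

    try:
        stage("mu")
        dom = uniqueness.dominance_table(rw, factors, range_rule=config.mu_range_rule)
        dom.table.to_csv(out / "mu_dominance.csv")
        dom.overall.to_frame("overall_mu").to_csv(out / "mu_overall.csv")
        mu_tests = {}
        rng = _substream(config.seed, "mu")
        for name, vals in factors.items():
            if len(set(vals)) == 2:
                res = uniqueness.mu_significance(
                    rw,
                    vals,
                    n_resamples=config.mu_resamples,
                    mode=config.mu_null_mode,
                    seed=rng,
                    range_rule=config.mu_range_rule,
                )
                mu_tests[name] = {
                    "overall_mu": res.overall_mu,
                    "p_value": res.p_value,
                    "n_resamples": res.n_resamples,
                }
            else:
                mat, mean = uniqueness.pairwise_mu(rw, vals, range_rule=config.mu_range_rule)
                mat.to_csv(out / f"mu_pairwise_{name}.csv")
                mu_tests[name] = {"mean_pairwise_mu": mean}
        (out / "mu_tests.json").write_text(json.dumps(mu_tests, indent=2))
        bundle["mu"] = {"dominance": dom, "tests": mu_tests}
    except Exception as exc:
        raise RuntimeError(f"stage 'mu' failed: {exc}") from exc

    try:
        stage("cluster")
        sel = mixtures.select_clusters(
            rw.scores,
            k_max=config.cluster_kmax,
            seed=config.seed,
            restarts=config.cluster_restarts,
            score_method=config.cluster_score,
        )
        sel.score_table.to_csv(out / "cluster_scores.csv")
        plot_df = mixtures.assignment_plot_data(
            sel.best, dataset.specimen_ids, order_by=factors.get("sex")
        )
        plot_df.to_csv(out / "cluster_assignments.csv", index=False)
        bundle["clustering"] = sel
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    try:
        stage("manova")
        if config.males_only and {"host", "population"} <= set(factors):
            res = linmodels.manova_nested(
                rw.scores[:, : min(rw.m, 18)], factors["host"], factors["population"]
            )
        elif {"sex", "population", "rearing"} <= set(factors):
            # reciprocal-transplant subset: lab-reared specimens from
            # populations reared on both hosts; rearing becomes the
            # host-rearing-condition factor (A vs C)
            rearing = factors["rearing"]
            pops = factors["population"]
            lab = np.isin(rearing, ["LAB-A", "LAB-C"])
            both = [
                p
                for p in sorted(set(pops))
                if {"LAB-A", "LAB-C"} <= set(rearing[lab & (pops == p)])
            ]
            sub = lab & np.isin(pops, both)
            if sub.sum() > resid.shape[1] + 8 and len(both) >= 2:
                hrc = np.where(rearing[sub] == "LAB-A", "A", "C")
                res = linmodels.manova(
                    resid[sub],
                    {"sex": factors["sex"][sub], "population": pops[sub], "hrc": hrc},
                    interactions=[("sex", "population"), ("sex", "hrc"), ("population", "hrc")],
                )
            else:
                res = linmodels.manova(resid, {"sex": factors["sex"]})
        elif len(factors) >= 1:
            res = linmodels.manova(resid, {next(iter(factors)): factors[next(iter(factors))]})
        else:
            res = []
        if res:
            linmodels.manova_table(res).to_csv(out / "manova.csv")
        bundle["manova"] = res
    except Exception as exc:
        raise RuntimeError(f"stage 'manova' failed: {exc}") from exc

    try:
        stage("geneflow")
        pops = dataset.factor("population")
        usable = [p for p in set(pops) if (pops == p).sum() >= 2 and p in config.influence]
        if len(usable) >= 3:
            disp = linmodels.dispersion_vs_influence(rw.scores, pops, config.influence)
            disp.sem_table.to_csv(out / "geneflow_sem.csv")
            disp.per_rw.to_csv(out / "geneflow_regression.csv")
            (out / "geneflow_mean_fit.json").write_text(json.dumps(disp.mean_sem_fit, indent=2))
            bundle["geneflow"] = disp
        else:
            bundle["geneflow"] = None
    except Exception as exc:
        raise RuntimeError(f"stage 'geneflow' failed: {exc}") from exc

    manifest = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
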