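"""End-to-end study workflow: simulate/load -> measure -> GPA -> species
means -> phylogenetic comparative statistics -> JSON report."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import arcs
from .data import (
    ClawConfiguration,
    LandmarkPartition,
    MetadataTable,
    Phylogeny,
    attach_metadata,
    prune_tree,
    read_newick,
    read_tps,
    species_means,
    write_tps,
)
from .errors import ClawMorphError, DegenerateGeometryError, ValidationError
from .phylo import (
    PhyloCovariance,
    compare_pls,
    design_matrix,
    k_mult,
    modularity_cr,
    pgls_ml_lambda,
    phylo_anova_sim,
    phylo_covariance,
    phylo_paired_t,
    phylo_procrustes_anova,
    phylo_two_block_pls,
)
from .shapestats import common_allometric_component, morphological_disparity, shape_pca
from .superimpose import gpa, slide_semilandmarks
from .synth import Scenario, simulate_dataset

log = logging.getLogger(__name__)

ALL_TESTS = (
    "pgls_traditional",
    "phylo_anova_traditional",
    "pca_species",
    "pca_individuals",
    "k_mult",
    "allometry",
    "phylo_procrustes_anova",
    "disparity",
    "pgls_core_sheath",
    "residual_anova",
    "paired_t",
    "modularity_cr",
    "pls_core_sheath",
    "compare_pls_groups",
    "pls_traditional_vs_gm",
)


@dataclass
class RunConfig:
    scenario: Scenario | None = None
    tps_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    slide: bool = True
    outer_iters: int = 3
    n_perm: int = 999
    n_sim: int = 1000
    seed: int = 0
    tests: tuple = ALL_TESTS
    output_dir: str | None = None
    ci_method: str = "t"

    def __post_init__(self):
        if self.n_perm < 99:
            raise ValidationError("n_perm must be at least 99")
        if self.scenario is None and self.tps_path is None:
            raise ValidationError("provide either a scenario or input paths")
        unknown = set(self.tests) - set(ALL_TESTS)
        if unknown:
            raise ValidationError(f"unknown tests requested: {sorted(unknown)}")

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.scenario is not None:
            d["scenario"] = asdict(self.scenario)
        d["tests"] = list(self.tests)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("scenario") is not None:
            sc = dict(d["scenario"])
            if "group_fractions" in sc:
                sc["group_fractions"] = tuple(sc["group_fractions"])
            if "bm_sd" in sc:
                sc["bm_sd"] = tuple(sc["bm_sd"])
            if "within_species_sd" in sc:
                sc["within_species_sd"] = tuple(sc["within_species_sd"])
            if "group_offsets" in sc:
                sc["group_offsets"] = {
                    k: tuple(v) for k, v in sc["group_offsets"].items()
                }
            d["scenario"] = Scenario(**sc)
        if "tests" in d:
            d["tests"] = tuple(d["tests"])
        return cls(**d)


def confidence_intervals(
    values, level: float = 0.95, method: str = "t"
) -> tuple[float, float]:
    """Two-sided CI for the mean: t-based (default) or percentile."""
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise ValidationError("confidence interval needs n >= 2")
    if method == "percentile":
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
        return float(lo), float(hi)
    mean = x.mean()
    half = sps.t.ppf(0.5 + level / 2.0, n - 1) * x.std(ddof=1) / math.sqrt(n)
    return float(mean - half), float(mean + half)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    return obj


class StageError(ClawMorphError):
    def __init__(self, stage: str, context: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the (JSON-serializable) report."""
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31)) for name in ALL_TESTS}
    report: dict = {
        "config": _jsonable(config.to_dict()),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "excluded_specimens": [],
        "tests": {},
    }
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage: load or simulate -----------------------------------------
    truth = None
    try:
        if config.scenario is not None:
            configs, metadata, tree, truth = simulate_dataset(
                config.scenario, seed=config.seed
            )
        else:
            configs = read_tps(config.tps_path)
            metadata = MetadataTable.read_csv(config.metadata_path)
            configs = attach_metadata(configs, metadata)
            tree = read_newick(config.tree_path)
    except Exception as exc:
        raise StageError("load", "input acquisition", exc) from exc
    report["n_specimens"] = len(configs)

    if outdir:
        write_tps(configs, outdir / "claws.tps")
        metadata.write_csv(outdir / "metadata.csv")
        tree.write_newick(outdir / "tree.nwk")
        if truth is not None:
            (outdir / "truth.json").write_text(
                json.dumps(_jsonable(truth.to_dict()), indent=1)
            )

    # ---- stage: traditional arc measurement ------------------------------
    measurements = {}
    kept_configs = []
    for cfg in configs:
        try:
            m = arcs.measure_configuration(cfg)
        except DegenerateGeometryError as exc:
            log.warning("excluding %s: %s", cfg.specimen_id, exc)
            report["excluded_specimens"].append(
                {"specimen_id": cfg.specimen_id, "reason": str(exc)}
            )
            continue
        measurements[cfg.specimen_id] = m
        kept_configs.append(cfg)
    if len(kept_configs) < 4:
        raise StageError("measure", "too few measurable specimens", ValidationError("n < 4"))
    configs = kept_configs
    trad = pd.DataFrame(
        {
            "specimen_id": list(measurements),
            "core_arc_deg": [m.core_arc_deg for m in measurements.values()],
            "sheath_arc_deg": [m.sheath_arc_deg for m in measurements.values()],
            "length_ratio": [m.length_ratio for m in measurements.values()],
        }
    )
    if outdir:
        trad.to_csv(outdir / "traditional_metrics.csv", index=False)

    # ---- stage: GPA (+ sliding) ------------------------------------------
    try:
        sample = gpa(configs)
        if config.slide:
            sample = slide_semilandmarks(sample, outer_iters=config.outer_iters)
    except Exception as exc:
        raise StageError("gpa", "superimposition", exc) from exc
    report["slide"] = config.slide
    if config.slide:
        report["bending_energy"] = _jsonable(sample.slide_info.get("bending_energy", []))
    if outdir:
        sample.to_frame().to_csv(outdir / "aligned.csv", index=False)

    # ---- stage: per-specimen summaries (individual variation) ------------
    trad_idx = trad.set_index("specimen_id")
    summaries = {"overall": {}}
    for col in ("core_arc_deg", "sheath_arc_deg", "length_ratio"):
        lo, hi = confidence_intervals(trad_idx[col], method=config.ci_method)
        summaries["overall"][col] = {
            "mean": float(trad_idx[col].mean()),
            "ci95": [lo, hi],
        }
    counts = metadata.table.groupby("species").size().sort_values(ascending=False)
    focal = list(counts.index[:4])
    summaries["focal_species"] = {}
    lut = metadata.table.set_index("specimen_id")["species"]
    for sp in focal:
        ids = [s for s in trad_idx.index if lut.get(s) == sp]
        if len(ids) < 2:
            continue
        entry = {"n": len(ids)}
        for col in ("core_arc_deg", "sheath_arc_deg", "length_ratio"):
            lo, hi = confidence_intervals(trad_idx.loc[ids, col], method=config.ci_method)
            entry[col] = {"mean": float(trad_idx.loc[ids, col].mean()), "ci95": [lo, hi]}
        summaries["focal_species"][sp] = entry
    report["traditional_summaries"] = _jsonable(summaries)

    tests = report["tests"]
    if "pca_individuals" in config.tests:
        pca_ind = shape_pca(sample)
        tests["pca_individuals"] = {
            "percent_variance": _jsonable(pca_ind.percent_variance[:10]),
        }
        if outdir:
            pd.DataFrame(
                pca_ind.scores[:, :5],
                index=sample.specimen_ids,
                columns=[f"PC{i + 1}" for i in range(min(5, pca_ind.scores.shape[1]))],
            ).to_csv(outdir / "pca_individuals.csv")

    # ---- stage: species means --------------------------------------------
    try:
        shape_df = pd.DataFrame(sample.flattened(), index=sample.specimen_ids)
        shape_means = species_means(shape_df, metadata)
        size_df = pd.DataFrame(
            {"centroid_size": sample.centroid_sizes}, index=sample.specimen_ids
        )
        size_means = species_means(size_df, metadata, log_columns=["centroid_size"])
        trad_means = species_means(trad, metadata)
    except Exception as exc:
        raise StageError("species_means", "aggregation", exc) from exc
    species = list(shape_means.index)
    ecology = shape_means["ecology"].to_numpy()
    Y = shape_means.drop(columns="ecology").to_numpy(float)
    log_cs = size_means["centroid_size"].to_numpy(float)
    report["n_species"] = len(species)

    # ---- stage: phylogeny -------------------------------------------------
    try:
        pruned = prune_tree(tree, species)
        cov = phylo_covariance(pruned, species)
    except Exception as exc:
        raise StageError("phylogeny", "prune/covariance", exc) from exc

    trad_cols = {
        "length_ratio": trad_means["length_ratio"].to_numpy(float),
        "log_core_arc": np.log(trad_means["core_arc_deg"].to_numpy(float)),
        "log_sheath_arc": np.log(trad_means["sheath_arc_deg"].to_numpy(float)),
    }

    def run_test(name, fn):
        if name not in config.tests:
            return
        try:
            tests[name] = fn()
        except Exception as exc:
            raise StageError(name, "statistical test", exc) from exc

    # PGLS of each traditional metric on log centroid size
    def _pgls_traditional():
        out = {}
        for metric, y in trad_cols.items():
            X, names = design_matrix(covariates={"log_centroid_size": log_cs})
            fit = pgls_ml_lambda(y, X, cov, coef_names=names)
            out[metric] = {
                "lambda_hat": fit.lambda_hat,
                "r2": fit.r2,
                "coefficients": dict(zip(fit.coef_names, fit.coefficients.tolist())),
                "p_values": dict(zip(fit.coef_names, fit.p_values.tolist())),
            }
        return _jsonable(out)

    run_test("pgls_traditional", _pgls_traditional)

    def _anova_traditional():
        out = {}
        for i, (metric, y) in enumerate(trad_cols.items()):
            res = phylo_anova_sim(
                y, ecology, cov, n_sim=config.n_sim,
                seed=seeds["phylo_anova_traditional"] + i,
            )
            out[metric] = res.summary()
        return _jsonable(out)

    run_test("phylo_anova_traditional", _anova_traditional)

    pca_sp = None
    if "pca_species" in config.tests:
        pca_sp = shape_pca(Y)
        # orient PC1 so increasing scores mean increasing claw curvature
        # (positive correlation with the sheath arc); the raw eigenvector
        # sign convention is data-driven and otherwise arbitrary
        pc1 = pca_sp.scores[:, 0]
        sheath = trad_means["sheath_arc_deg"].to_numpy(float)
        flip = -1.0 if np.corrcoef(pc1, sheath)[0, 1] < 0 else 1.0
        group_centroids = {
            g: float((flip * pc1)[ecology == g].mean())
            for g in sorted(set(ecology.tolist()))
        }
        tests["pca_species"] = _jsonable(
            {
                "percent_variance": pca_sp.percent_variance[:10],
                "pc1_group_centroids": group_centroids,
                "pc1_oriented_by": "sheath_arc_deg",
            }
        )
        if outdir:
            pd.DataFrame(
                pca_sp.scores[:, :5],
                index=species,
                columns=[f"PC{i + 1}" for i in range(min(5, pca_sp.scores.shape[1]))],
            ).to_csv(outdir / "pca_species.csv")

    run_test(
        "k_mult",
        lambda: k_mult(Y, cov, n_perm=config.n_perm, seed=seeds["k_mult"]).summary(),
    )

    def _allometry():
        from .superimpose import ShapeSample

        mean_sample = ShapeSample(
            aligned=Y.reshape(len(species), -1, 2),
            centroid_sizes=np.exp(log_cs),
            mean_shape=Y.mean(axis=0).reshape(-1, 2),
            specimen_ids=species,
        )
        res = common_allometric_component(
            mean_sample, n_perm=config.n_perm, seed=seeds["allometry"]
        )
        return _jsonable(
            {"r2": res.r2, "p_value": res.p_value, "n_perm": res.n_perm, "seed": res.seed}
        )

    run_test("allometry", _allometry)

    def _ppa():
        res = phylo_procrustes_anova(
            Y, log_cs, ecology, cov, n_perm=config.n_perm,
            seed=seeds["phylo_procrustes_anova"],
        )
        return _jsonable({term: r.summary() for term, r in res.items()})

    run_test("phylo_procrustes_anova", _ppa)

    def _disparity():
        res = morphological_disparity(
            Y, ecology, n_perm=config.n_perm, seed=seeds["disparity"]
        )
        return _jsonable(
            {
                "group_pv": res.group_pv,
                "pairwise_p": {f"{a}|{b}": p for (a, b), p in res.pairwise_p.items()},
                "n_perm": res.n_perm,
                "seed": res.seed,
            }
        )

    run_test("disparity", _disparity)

    # core-vs-sheath traditional relationship
    core_sheath_fit = {}

    def _pgls_core_sheath():
        X, names = design_matrix(
            covariates={
                "log_core_arc": trad_cols["log_core_arc"],
                "log_centroid_size": log_cs,
            }
        )
        fit = pgls_ml_lambda(trad_cols["log_sheath_arc"], X, cov, coef_names=names)
        core_sheath_fit["residuals"] = fit.residuals
        return _jsonable(
            {
                "lambda_hat": fit.lambda_hat,
                "slope_m": fit.coefficients[1],
                "r2": fit.r2,
                "p_values": dict(zip(fit.coef_names, fit.p_values.tolist())),
            }
        )

    run_test("pgls_core_sheath", _pgls_core_sheath)

    def _residual_anova():
        if "residuals" not in core_sheath_fit:
            X, _ = design_matrix(
                covariates={
                    "log_core_arc": trad_cols["log_core_arc"],
                    "log_centroid_size": log_cs,
                }
            )
            fit = pgls_ml_lambda(trad_cols["log_sheath_arc"], X, cov)
            core_sheath_fit["residuals"] = fit.residuals
        res = phylo_anova_sim(
            core_sheath_fit["residuals"], ecology, cov,
            n_sim=config.n_sim, seed=seeds["residual_anova"],
        )
        return _jsonable(res.summary())

    run_test("residual_anova", _residual_anova)

    run_test(
        "paired_t",
        lambda: _jsonable(
            phylo_paired_t(
                trad_cols["log_sheath_arc"], trad_cols["log_core_arc"], cov
            ).summary()
        ),
    )

    partition = LandmarkPartition.default()
    core_cols = np.sort(
        np.concatenate([2 * partition.core_array(), 2 * partition.core_array() + 1])
    )
    sheath_cols = np.sort(
        np.concatenate([2 * partition.sheath_array(), 2 * partition.sheath_array() + 1])
    )

    run_test(
        "modularity_cr",
        lambda: _jsonable(
            modularity_cr(
                Y, partition, cov, n_perm=config.n_perm, seed=seeds["modularity_cr"]
            ).summary()
        ),
    )

    pls_store = {}

    def _pls_core_sheath():
        res = phylo_two_block_pls(
            Y[:, core_cols], Y[:, sheath_cols], cov,
            n_perm=config.n_perm, seed=seeds["pls_core_sheath"],
        )
        pls_store["all"] = res
        s = res.summary()
        s["details"] = {
            k: v
            for k, v in s["details"].items()
            if k in ("fisher_z", "fisher_z_null_sd", "fisher_z_null_mean")
        }
        return _jsonable(s)

    run_test("pls_core_sheath", _pls_core_sheath)

    def _compare_pls_groups():
        group_results = {}
        skipped = {}
        for g in sorted(set(ecology.tolist())):
            members = [sp for sp, e in zip(species, ecology) if e == g]
            if len(members) < 4:
                skipped[g] = f"only {len(members)} species"
                continue
            idx = [species.index(sp) for sp in members]
            sub_cov = phylo_covariance(prune_tree(pruned, members), members)
            group_results[g] = phylo_two_block_pls(
                Y[np.ix_(idx, core_cols)],
                Y[np.ix_(idx, sheath_cols)],
                sub_cov,
                n_perm=config.n_perm,
                seed=seeds["compare_pls_groups"],
            )
        out = {"skipped": skipped}
        if len(group_results) >= 2:
            table = compare_pls(group_results)
            out["pairwise"] = table.to_dict(orient="records")
            out["r_pls"] = {g: r.statistic for g, r in group_results.items()}
            out["effect_size_z"] = {
                g: r.effect_size_z for g, r in group_results.items()
            }
        return _jsonable(out)

    run_test("compare_pls_groups", _compare_pls_groups)

    def _pls_trad_gm():
        block1 = np.column_stack(
            [
                trad_cols["length_ratio"],
                trad_cols["log_core_arc"],
                trad_cols["log_sheath_arc"],
            ]
        )
        res = phylo_two_block_pls(
            block1, Y, cov, n_perm=config.n_perm, seed=seeds["pls_traditional_vs_gm"]
        )
        s = res.summary()
        s["details"] = {
            k: v
            for k, v in s["details"].items()
            if k in ("fisher_z", "fisher_z_null_sd", "fisher_z_null_mean")
        }
        return _jsonable(s)

    run_test("pls_traditional_vs_gm", _pls_trad_gm)

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
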