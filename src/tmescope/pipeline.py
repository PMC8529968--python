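"""End-to-end orchestration of the simulation/deconvolution/prognosis pipeline.

A single flat YAML config drives all stages; every stage derives its RNG seed
deterministically from the master seed, and a manifest JSON records the
parameterization, per-output SHA-256 hashes and the config hash so a rerun
with the same seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .assoc import associate
from .deconv import DeconvOptions, deconvolve, evaluate_deconv
from .gsets import activation_scores, write_gmt
from .rgep import (MarkerCriteria, QCThresholds, build_rgep, cpm, find_markers,
                   merge_signature_sets, normalize_bulk, normalize_sc, qc_filter_cells)
from .sim import (ExprTemplate, SCSimConfig, SurvCohortTruth, simulate_cell_pool,
                  simulate_gene_sets, simulate_mixtures, simulate_survival_cohort)
from .survival import (SurvivalData, build_risk_model, km_estimate, log_rank,
                       optimal_cutpoint, risk_score)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("tmescope.pipeline")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

ALL_STAGES = ["pool", "rgep", "mixtures", "deconv", "cohort", "score", "associate",
              "fit", "stratify"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # pool
    n_types: int = 8
    n_genes: int = 1200
    cells_per_type: int = 120
    markers_per_type: int = 20
    marker_logfc: float = 2.0
    nb_dispersion: float = 0.3
    libsize_low: int = 1000
    libsize_high: int = 5000
    frac_qc_fail: float = 0.02
    # QC / markers
    min_genes: int = 200
    max_genes: int = 3000
    min_umis: int = 500
    max_umis: int = 10000
    logfc_threshold: float = 0.5
    min_pct: float = 0.1
    max_adj_p: float = 0.05
    # mixtures
    n_mixtures: int = 60
    cells_per_sample: int = 2000
    dirichlet_alpha: float = 1.0
    # deconvolution
    robust_loss: str = "tukey_bisquare"
    # gene sets / cohort
    n_gene_sets: int = 120
    set_size_low: int = 10
    set_size_high: int = 40
    n_cohort: int = 160
    n_designated: int = 2
    beta_true: float = 1.2
    effect_size: float = 2.0
    couple_strength: float = 0.95
    censor_rate: float = 0.3
    # cohort composition: designated sets couple to rare cell types (small
    # Dirichlet concentration), where the aggregated Fisher-Z statistic is
    # least attenuated by simplex closure
    cohort_alpha_rare: float = 0.3
    cohort_alpha_common: float = 1.5
    sample_noise_sigma: float = 0.2
    # screen / model
    screen_alpha: float = 0.01
    screen_types: str = "lasso"   # 'lasso' (proportion-model subset) or 'all'
    n_folds: int = 5
    minprop: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise PipelineError(f"config: unknown stages {bad}")
        if self.seed < 0 or self.seed >= 2**31:
            raise PipelineError("config: seed must be in [0, 2^31)")

    def hash(self) -> str:
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(path: Path, stage: str, what: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"{stage}: missing input {path.name} ({what}); did you skip its stage?"
        )
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order and return the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    stage_seed = {s: (seed + 1000 * (i + 1)) % (2**31 - 1) for i, s in enumerate(ALL_STAGES)}
    manifest: dict = {"config": asdict(config), "config_hash": config.hash(), "stages": {}}

    def done(stage, **outputs):
        manifest["stages"][stage] = {
            "seed": stage_seed[stage],
            "outputs": {k: _sha256(Path(v)) for k, v in outputs.items()},
        }
        log.info("%s: done (%s)", stage, ", ".join(Path(v).name for v in outputs.values()))

    if "pool" in config.stages:
        cfg = SCSimConfig(
            n_types=config.n_types, n_genes=config.n_genes,
            cells_per_type=config.cells_per_type,
            markers_per_type=config.markers_per_type,
            marker_logfc=config.marker_logfc, nb_dispersion=config.nb_dispersion,
            libsize_range=(config.libsize_low, config.libsize_high),
            frac_qc_fail=config.frac_qc_fail, seed=stage_seed["pool"],
        )
        pool = simulate_cell_pool(cfg)
        tio.write_pool(pool, out / "pool")
        done("pool", matrix=out / "pool" / "matrix.mtx", labels=out / "pool" / "labels.tsv")

    if "rgep" in config.stages:
        pool = tio.read_pool(_require(out / "pool", "rgep", "single-cell pool").parent / "pool")
        thr = QCThresholds(config.min_genes, config.max_genes, config.min_umis, config.max_umis)
        counts, kept = qc_filter_cells(pool.counts, thr)
        labels = pool.labels.loc[kept]
        norm = normalize_sc(counts)
        markers = find_markers(norm, labels, MarkerCriteria(
            config.logfc_threshold, config.min_pct, config.max_adj_p))
        sig, _ = merge_signature_sets([markers["gene"].tolist()], universe=list(counts.index))
        rgep = build_rgep(counts, labels, sig, scale="linear_cpm")
        rgep.to_tsv(out / "rgep.tsv", sidecar=out / "rgep.json")
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        done("rgep", rgep=out / "rgep.tsv", markers=out / "markers.tsv")

    if "mixtures" in config.stages:
        pool = tio.read_pool(_require(out / "pool", "mixtures", "single-cell pool").parent / "pool")
        bulk, truth = simulate_mixtures(
            pool, config.n_mixtures, config.cells_per_sample,
            np.full(len(pool.types), config.dirichlet_alpha), seed=stage_seed["mixtures"],
        )
        tio.write_matrix_tsv(bulk, out / "mix_bulk.tsv")
        tio.write_matrix_tsv(truth.proportions, out / "mix_truth.tsv", index_label="sample")
        done("mixtures", bulk=out / "mix_bulk.tsv", truth=out / "mix_truth.tsv")

    if "deconv" in config.stages:
        from .rgep import RGEP
        rgep = RGEP.from_tsv(_require(out / "rgep.tsv", "deconv", "reference profile"))
        bulk = tio.read_matrix_tsv(_require(out / "mix_bulk.tsv", "deconv", "mixture bulk"))
        res = deconvolve(cpm(bulk), rgep, DeconvOptions(robust_loss=config.robust_loss))
        truth_df = tio.read_matrix_tsv(out / "mix_truth.tsv")
        metrics = evaluate_deconv(truth_df, res.proportions)
        tio.write_matrix_tsv(res.proportions, out / "mix_props.tsv", index_label="sample")
        tio.write_json(
            {"pearson_r_pooled": metrics.pearson_r_pooled, "rmse": metrics.rmse,
             "config_hash": config.hash(), "seed": seed},
            out / "deconv_metrics.json",
        )
        done("deconv", props=out / "mix_props.tsv", metrics=out / "deconv_metrics.json")

    if "cohort" in config.stages:
        pool = tio.read_pool(_require(out / "pool", "cohort", "single-cell pool").parent / "pool")
        rng = np.random.default_rng(stage_seed["cohort"])
        # designated prognostic sets drawn from non-marker genes so the
        # deconvolution basis stays clean
        marker_genes = {g for gs in pool.truth.values() for g in gs}
        free = [g for g in pool.gene_ids if g not in marker_genes]
        designated = {}
        for i in range(config.n_designated):
            designated[f"DESIGNATED_{i}"] = list(
                np.asarray(free)[rng.choice(len(free), config.set_size_high, replace=False)])
        # background sets also come from non-marker genes: sets overlapping the
        # planted marker panel are genuinely composition-associated and would
        # not be a null background for the screen
        coll = simulate_gene_sets(
            free, n_sets=config.n_gene_sets,
            size_range=(config.set_size_low, config.set_size_high),
            seed=stage_seed["cohort"], designated=designated,
        )
        write_gmt(coll, out / "gene_sets.gmt")
        truth = SurvCohortTruth(
            beta_true={k: config.beta_true * (-1) ** i for i, k in enumerate(designated)},
            censor_rate=config.censor_rate, seed=stage_seed["cohort"],
        )
        alpha = np.full(len(pool.types), config.cohort_alpha_common)
        alpha[: config.n_designated] = config.cohort_alpha_rare
        tpl = ExprTemplate(
            pool=pool, alpha=alpha, cells_per_sample=config.cells_per_sample,
            effect_size=config.effect_size,
            couple_to={k: pool.types[i % len(pool.types)] for i, k in enumerate(designated)},
            couple_strength=config.couple_strength,
            sample_noise_sigma=config.sample_noise_sigma,
        )
        cohort = simulate_survival_cohort(config.n_cohort, coll, truth, tpl)
        tio.write_matrix_tsv(cohort.bulk, out / "cohort_bulk.tsv")
        tio.write_survival_tsv(cohort.survival, out / "cohort_surv.tsv")
        tio.write_json(
            {"beta_true": truth.beta_true,
             "designated": {k: list(v) for k, v in designated.items()},
             "latent_risk": cohort.latent_risk.to_dict(), "seed": stage_seed["cohort"]},
            out / "cohort_truth.json",
        )
        done("cohort", bulk=out / "cohort_bulk.tsv", surv=out / "cohort_surv.tsv",
             gmt=out / "gene_sets.gmt")

    if "score" in config.stages:
        from .gsets import read_gmt
        bulk = tio.read_matrix_tsv(_require(out / "cohort_bulk.tsv", "score", "cohort bulk"))
        coll = read_gmt(_require(out / "gene_sets.gmt", "score", "gene sets"))
        logexpr = normalize_bulk(bulk)
        act = activation_scores(logexpr, coll, kernel="gaussian", tau=1.0)
        tio.write_matrix_tsv(act.scores, out / "activations.tsv", index_label="gene_set")
        tio.write_json(act.metadata | {"config_hash": config.hash()}, out / "activations.json")
        done("score", scores=out / "activations.tsv")

    if "associate" in config.stages:
        from .rgep import RGEP
        rgep = RGEP.from_tsv(_require(out / "rgep.tsv", "associate", "reference profile"))
        bulk = tio.read_matrix_tsv(_require(out / "cohort_bulk.tsv", "associate", "cohort bulk"))
        act = tio.read_matrix_tsv(_require(out / "activations.tsv", "associate", "activation scores"))
        res = deconvolve(cpm(bulk), rgep, DeconvOptions(robust_loss=config.robust_loss))
        props = res.proportions
        tio.write_matrix_tsv(props, out / "cohort_props.tsv", index_label="sample")
        surv = tio.read_survival_tsv(out / "cohort_surv.tsv")
        types_used = list(props.columns)
        if config.screen_types == "lasso":
            # proportion-based model first: LASSO-Cox picks the cell types
            # that enter the screen (and is itself a reported model)
            pdata = SurvivalData.from_frames(surv, props)
            try:
                pmodel, pfit = build_risk_model(pdata, n_folds=config.n_folds,
                                                seed=stage_seed["associate"])
                types_used = pmodel.features
                tio.write_json(
                    {"features": pmodel.features, "beta": pmodel.beta.to_dict(),
                     "concordance": pfit.concordance, **pmodel.metadata},
                    out / "proportion_model.json",
                )
            except ValueError as err:
                log.info("associate: proportion-model selection fell back to all types (%s)", err)
        table, report = associate(act, props[types_used], alpha=config.screen_alpha)
        table.to_csv(out / "association.tsv", sep="\t", index_label="gene_set")
        tio.write_json(report | {"types_used": list(types_used)}, out / "association.json")
        done("associate", table=out / "association.tsv")

    if "fit" in config.stages:
        table = tio.read_matrix_tsv(_require(out / "association.tsv", "fit", "association table"))
        act = tio.read_matrix_tsv(_require(out / "activations.tsv", "fit", "activation scores"))
        surv = tio.read_survival_tsv(_require(out / "cohort_surv.tsv", "fit", "survival table"))
        selected = table.index[table["selected"].astype(bool)].tolist()
        if not selected:
            raise PipelineError("fit: association screen selected no gene sets")
        data = SurvivalData.from_frames(surv, act.loc[selected].T)
        model, fit = build_risk_model(data, n_folds=config.n_folds, seed=stage_seed["fit"])
        scores = risk_score(model, data.features)
        tio.write_json(
            {"features": model.features, "beta": model.beta.to_dict(),
             "hazard_ratio": fit.hazard_ratio.to_dict(), "concordance": fit.concordance,
             **model.metadata, "config_hash": config.hash()},
            out / "function_model.json",
        )
        scores.rename("risk_score").to_frame().to_csv(out / "risk_scores.tsv", sep="\t",
                                                      index_label="sample")
        done("fit", model=out / "function_model.json", scores=out / "risk_scores.tsv")

    if "stratify" in config.stages:
        scores = tio.read_matrix_tsv(_require(out / "risk_scores.tsv", "stratify", "risk scores"))
        surv = tio.read_survival_tsv(out / "cohort_surv.tsv").set_index("sample")
        surv = surv.loc[scores.index]
        cut = optimal_cutpoint(scores["risk_score"], surv["time"], surv["event"],
                               minprop=config.minprop)
        groups = np.where(scores["risk_score"] > cut.threshold, "high", "low")
        chi2, dof, p = log_rank(surv["time"], surv["event"], groups)
        curves = km_estimate(surv["time"], surv["event"], groups)
        tio.write_json(
            {"cutpoint": cut.threshold, "max_statistic": cut.statistic,
             "n_low": cut.n_low, "n_high": cut.n_high,
             "log_rank_chi2": chi2, "df": dof, "p": p,
             "km": {g: c.to_dict(orient="list") for g, c in curves.items()},
             "config_hash": config.hash(), "seed": seed},
            out / "stratification.json",
        )
        done("stratify", report=out / "stratification.json")

    tio.write_json(manifest, out / "manifest.json")
    return manifest
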