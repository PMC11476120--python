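"""End-to-end orchestration: simulate -> preprocess/QC -> calibrate ->
predict -> correct -> REML/EBV -> GWAS -> validate, from one config.

Every stochastic stage derives its seed from the global seed and the stage
name, so a rerun with the same config reproduces the same manifest counts
and the same significant-SNP list.  The manifest records parameters, seeds
and row counts at every filtering step.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, genparams, gwas, phenocorrect, snpvalidate, spectra
from .simdata import (SimConfig, default_component_profiles, simulate_genotypes,
                      simulate_pedigree, simulate_phenotypes, simulate_spectra,
                      write_outputs)

DEFAULT_STAGES = ("simulate", "preprocess", "calibrate", "predict", "correct",
                  "genparams", "gwas", "validate")


@dataclass
class PipelineConfig:
    outdir: str = "mirfa_run"
    seed: int = 0
    stages: tuple = DEFAULT_STAGES
    sim: dict = field(default_factory=dict)
    noise_sd: float = 0.002
    qc: dict = field(default_factory=dict)
    calibrate: dict = field(default_factory=lambda: {
        "recipes": ("D1+D1", "D2+D2"), "components": (8, 10),
        "n_keeps": (600,), "k": 10})
    reml: dict = field(default_factory=lambda: {"kinship": "A"})
    gwas: dict = field(default_factory=lambda: {"model": "farmcpu", "pcs": 3,
                                                "alpha": 0.05})
    validate_fraction: float = 0.2

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Global-seed fan-out by stage-name hashing."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": list(cfg.stages),
                      "counts": {}, "params": {}, "results": {}}
    t0 = time.time()
    log_lines = []

    def log(stage, msg):
        log_lines.append(f"[{time.time() - t0:8.1f}s] {stage}: {msg}")

    state: dict = {}
    for stage in cfg.stages:
        try:
            _STAGE_FUNCS[stage](cfg, state, manifest, log)
        except Exception as err:
            log(stage, f"FAILED: {err}")
            (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        log(stage, "done")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return manifest


# ----------------------------------------------------------------------------
# stages


def _simulate(cfg: PipelineConfig, state, manifest, log):
    sim = SimConfig(**{"n_founders": 100, "n_generations": 2,
                       "matings_per_generation": 250, "n_snps": 800,
                       **cfg.sim, "seed": stage_seed(cfg.seed, "simulate")})
    ped = simulate_pedigree(sim)
    geno = simulate_genotypes(ped, sim)
    records, truth = simulate_phenotypes(ped, geno, sim)
    rng = np.random.default_rng(stage_seed(cfg.seed, "simulate-aux"))
    n = len(records)
    records["sample_id"] = [f"S{i+1:05d}" for i in range(n)]
    # auxiliary composition + QC fields for the sample-screening rules
    records["fat_pct"] = np.clip(rng.normal(4.0, 0.9, n), 0.5, 12.0)
    records["protein_pct"] = np.clip(rng.normal(3.4, 0.4, n), 0.5, 9.0)
    records["scc"] = rng.lognormal(11.5, 0.9, n)
    # duplicate wet-chemistry reference measurements: 5% relative error each;
    # their mean is the reference value the calibration is trained against
    records["dup1"] = records["y"] * (1 + rng.normal(0.0, 0.05, n))
    records["dup2"] = records["y"] * (1 + rng.normal(0.0, 0.05, n))
    records["y_ref"] = 0.5 * (records["dup1"] + records["dup2"])
    # nuisance milk components sharing the spectral space with the trait
    records["comp2"] = rng.lognormal(0.0, 0.3, n)
    records["comp3"] = rng.lognormal(0.5, 0.2, n)
    profiles = default_component_profiles(["y", "comp2", "comp3"])
    spec = simulate_spectra(records, profiles, noise_sd=cfg.noise_sd,
                            seed=stage_seed(cfg.seed, "spectra"))
    write_outputs(Path(cfg.outdir) / "data", ped, geno, records, truth, spec)
    state.update(ped=ped, geno=geno, records=records, truth=truth, spec=spec,
                 sim=sim)
    manifest["params"]["sim"] = {k: v for k, v in asdict(sim).items()}
    manifest["counts"]["animals"] = len(ped)
    manifest["counts"]["records"] = n
    log("simulate", f"{len(ped)} animals, {n} records, {geno.n_snps} SNPs")


def _preprocess(cfg: PipelineConfig, state, manifest, log):
    rules = spectra.QCRule(**cfg.qc)
    records = state["records"]
    gh, _ = spectra.gh_filter(state["spec"],
                              n_components=min(10, state["spec"].n_samples - 2))
    records = records.assign(gh=gh)
    kept, rejlog = spectra.qc_records(records, rules)
    keep_mask = records["sample_id"].isin(kept["sample_id"]).to_numpy()
    state["records_qc"] = kept.reset_index(drop=True)
    state["spec_qc"] = state["spec"].subset(keep_mask)
    rejlog.to_csv(Path(cfg.outdir) / "qc_rejections.tsv", sep="\t", index=False)
    manifest["counts"]["records_after_qc"] = len(kept)
    manifest["counts"]["records_rejected"] = len(records) - len(kept)
    log("preprocess", f"{len(records)} -> {len(kept)} records after QC")


def _calibrate(cfg: PipelineConfig, state, manifest, log):
    rec = state["records_qc"]
    spec = state["spec_qc"]
    # reference subset: one sample per cow plays the wet-chemistry role
    ref_idx = rec.groupby("animal").head(1).index.to_numpy()
    ref_ids = rec.loc[ref_idx, "sample_id"].to_numpy()
    seed = stage_seed(cfg.seed, "calibrate")
    train_ids, test_ids = calibration.split_train_test(ref_ids, 0.75, seed)
    tr_mask = rec["sample_id"].isin(train_ids).to_numpy()
    te_mask = rec["sample_id"].isin(test_ids).to_numpy()
    y = rec["y_ref"].to_numpy(float)
    model = calibration.select_model(
        spec.subset(tr_mask), y[tr_mask], trait="y", seed=seed,
        test_spectra=spec.subset(te_mask), test_y=y[te_mask],
        **cfg.calibrate)
    calibration.save_model(Path(cfg.outdir) / "models", model)
    state["model"] = model
    manifest["results"]["calibration"] = vars(model.metrics)
    manifest["counts"]["calibration_train"] = len(train_ids)
    manifest["counts"]["calibration_test"] = len(test_ids)
    log("calibrate", f"recipe={model.recipe} ncomp={model.n_components} "
        f"R2_cv={model.metrics.r2_cv:.3f} R2_t={model.metrics.r2_t:.3f}")


def _predict(cfg: PipelineConfig, state, manifest, log):
    pred = calibration.predict_traits([state["model"]], state["spec_qc"])
    rec = state["records_qc"].copy()
    rec["y_pred"] = pred["y"].to_numpy()
    rec.to_csv(Path(cfg.outdir) / "predicted_records.tsv", sep="\t",
               index=False)
    state["records_pred"] = rec
    manifest["counts"]["predicted_records"] = len(rec)


def _correct(cfg: PipelineConfig, state, manifest, log):
    rec = phenocorrect.add_level_columns(state["records_pred"])
    model, fit = phenocorrect.fit_correction(rec, trait="y_pred")
    corrected = phenocorrect.corrected_phenotype(rec, model)
    corrected.to_csv(Path(cfg.outdir) / "corrected_phenotypes.tsv", sep="\t")
    state["records_lvl"] = rec
    state["corrected"] = corrected
    manifest["results"]["correction"] = {
        "mu": model.mu, "htd_variance": model.htd_variance,
        "residual_variance": model.residual_variance}
    manifest["counts"]["cows_with_corrected_phenotype"] = len(corrected)
    log("correct", f"mu={model.mu:.3f}")


def _genparams(cfg: PipelineConfig, state, manifest, log):
    rec = state["records_lvl"]
    ped = state["ped"]
    A = genparams.build_A(ped)
    kin = cfg.reml.get("kinship", "A")
    if kin == "A":
        K = A
    elif kin == "G":
        K = genparams.build_G(state["geno"])
    else:  # single-step H
        G = genparams.build_G(state["geno"])
        K = genparams.build_H_inverse(A, G)
    vc, fit = genparams.reml_fit(rec, K, value_col="y_pred")
    params = genparams.genetic_parameters(vc)
    ebv = genparams.ebv_solve(rec, vc, K, value_col="y_pred",
                              corrected=state["corrected"])
    ebv.table.to_csv(Path(cfg.outdir) / "ebv.tsv", sep="\t", index=False)
    state["vc"] = vc
    manifest["results"]["genparams"] = {
        "sigma_u2": vc.sigma_u2, "sigma_c2": vc.sigma_c2,
        "sigma_e2": vc.sigma_e2, "sigma_p2": vc.sigma_p2,
        "h2": params["h2"], "t": params["t"],
        "converged": vc.converged, "n_iter": vc.n_iter,
        "ebv": ebv.summary()}
    log("genparams", f"h2={params['h2']:.3f} t={params['t']:.3f} "
        f"acc={ebv.accuracy:.3f}")


def _gwas(cfg: PipelineConfig, state, manifest, log):
    geno = state["geno"]
    corrected = state["corrected"]
    rng = np.random.default_rng(stage_seed(cfg.seed, "gwas-split"))
    cows = np.array(sorted(corrected.index))
    n_val = int(round(cfg.validate_fraction * len(cows)))
    val_cows = set(rng.choice(cows, n_val, replace=False).tolist())
    gwas_cows = [c for c in cows if c not in val_cows]
    state["val_cows"] = sorted(val_cows)

    amask = np.isin(geno.animal_ids, gwas_cows)
    g = geno.subset_animals(amask)
    g, report = gwas.snp_qc(g, gwas.QCConfig(**{k: v for k, v in
                                                cfg.gwas.items()
                                                if k in ("call_rate", "hwe_p")}))
    pheno = corrected.loc[list(g.animal_ids)].to_numpy(float)
    pcs = gwas.pca_covariates(g, k=cfg.gwas.get("pcs", 3))
    model = cfg.gwas.get("model", "farmcpu")
    alpha = cfg.gwas.get("alpha", 0.05)
    if model == "glm":
        res = gwas.glm_scan(pheno, g, pcs, alpha=alpha)
    elif model == "mlm":
        K = genparams.build_G(g).matrix
        res = gwas.mlm_scan(pheno, g, pcs, K, alpha=alpha)
    else:
        res = gwas.farmcpu_scan(pheno, g, pcs, alpha=alpha)
    res.table.to_csv(Path(cfg.outdir) / "gwas_results.tsv", sep="\t",
                     index=False)
    gwas.export_qq(res, Path(cfg.outdir) / "gwas_qq.tsv")
    state["gwas_result"] = res
    state["geno_qc"] = g
    manifest["counts"]["gwas"] = report
    manifest["results"]["gwas"] = {
        "model": res.model, "threshold": res.threshold,
        "n_significant": int(res.table["significant"].sum()),
        "significant_snps": res.significant["snp"].tolist(),
        "lambda_gc": res.lambda_gc()}
    log("gwas", f"{model}: {int(res.table['significant'].sum())} significant "
        f"SNPs of {g.n_snps}")


def _validate(cfg: PipelineConfig, state, manifest, log):
    res = state["gwas_result"]
    cand = res.significant["snp"].tolist()
    if not cand:  # fall back to the top SNPs so the stage still demonstrates
        cand = res.table.nsmallest(3, "p")["snp"].tolist()
    geno = state["geno"]
    val_cows = state["val_cows"]
    amask = np.isin(geno.animal_ids, val_cows)
    g = geno.subset_animals(amask)
    classes = {0: "AA", 1: "AB", 2: "BB"}
    rows = []
    spos = {s: j for j, s in enumerate(g.snp_ids)}
    for snp in cand:
        j = spos[snp]
        for i, a in enumerate(g.animal_ids):
            d = g.dosage[i, j]
            if np.isfinite(d):
                rows.append((str(a), snp, classes[int(d)]))
    gtab = pd.DataFrame(rows, columns=["sample", "snp", "genotype"])
    ttab = pd.DataFrame({"sample": [str(a) for a in val_cows],
                         "trait": state["corrected"].loc[val_cows].to_numpy()})
    results = snpvalidate.validate_snps(gtab, ttab, "trait")
    table = snpvalidate.validation_table(results)
    table.to_csv(Path(cfg.outdir) / "validation.tsv", sep="\t", index=False)
    manifest["counts"]["validation_cows"] = len(val_cows)
    manifest["results"]["validation"] = {
        "n_candidates": len(cand),
        "n_confirmed": int((table["p_bonferroni"] < 0.05).sum())
        if len(table) else 0}
    log("validate", f"{len(cand)} candidates, "
        f"{manifest['results']['validation']['n_confirmed']} confirmed")


_STAGE_FUNCS = {
    "simulate": _simulate,
    "preprocess": _preprocess,
    "calibrate": _calibrate,
    "predict": _predict,
    "correct": _correct,
    "genparams": _genparams,
    "gwas": _gwas,
    "validate": _validate,
}
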