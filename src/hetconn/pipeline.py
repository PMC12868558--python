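"""End-to-end orchestration of the synthetic demo pipeline.

``run_pipeline`` executes every stage on generated data: BOLD simulation ->
heterogeneous factorization -> meta-BOLD connectivity -> cohort simulation ->
shared-pattern PLS and deviation profiles -> transcriptomic and feature
annotation -> stability validation.  All randomness flows from the single
config seed through named substreams, so a rerun with the same config
reproduces every output bit-identically; the manifest records parameter and
result hashes to make that checkable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synth, hmf as hmf_mod, connectome, stacp as stacp_mod, \
    validation as valid_mod, transcriptomics as tx, features as feat_mod
from .io import write_json

__all__ = ["RunConfig", "run_pipeline", "default_demo_config",
           "resolve_cohort_config"]


@dataclass
class RunConfig:
    seed: int = 7
    output_dir: str | None = None
    bold: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    annotation: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items()
                      if k in cls.__dataclass_fields__})


def default_demo_config() -> RunConfig:
    """Small, fast demo configuration exercising every stage."""
    return RunConfig(
        seed=7,
        bold=dict(n_subjects=8, n_regions=30, n_timepoints=60,
                  rank_shared=4, rank_specific=2, noise_fraction=0.02),
        cohort=dict(
            n_per_group={"HC": 60, "ASD": 60, "ADHD": 60, "SCZ": 60},
            n_edges=45, effect_size=0.8,
            deviation_gram="closed:-0.9",
            noise_sd=1.0, clinical_coupling=0.5),
        annotation=dict(n_regions=40, n_variables=120, n_features=8,
                        n_perm=100, n_boot=100),
        validation=dict(n_boot=100, k=5, n_perm=100, n_splits=20),
    )


def resolve_cohort_config(cohort_cfg: dict) -> dict:
    """Expand the ``deviation_gram='closed:<cos>'`` shorthand.

    The shorthand requests the closed three-disorder geometry (see
    :func:`hetconn.synth.closed_deviation_geometry`) in which the first two
    deviation directions have the given pairwise cosine and the geometry is
    exactly recoverable by the residual-projection pipeline.
    """
    cfg = dict(cohort_cfg)
    gram = cfg.get("deviation_gram")
    if isinstance(gram, str) and gram.startswith("closed:"):
        pair_cos = float(gram.split(":", 1)[1])
        disorders = [g for g in cfg["n_per_group"]
                     if g != "HC" and cfg["n_per_group"][g] > 0]
        counts = tuple(cfg["n_per_group"][d] for d in disorders)
        G, mags = synth.closed_deviation_geometry(pair_cos,
                                                  n_per_disorder=counts)
        cfg["deviation_gram"] = G
        cfg["deviation_magnitudes"] = dict(zip(disorders, mags))
    elif gram is not None:
        cfg["deviation_gram"] = np.asarray(gram, float)
    return cfg


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def run_pipeline(config: RunConfig | dict | None = None) -> dict:
    """Run the full synthetic pipeline; returns a result bundle.

    The bundle contains per-stage results plus a manifest with sha256
    hashes of every numeric output (used by the determinism check) and
    stage durations.
    """
    if config is None:
        config = default_demo_config()
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    seed = int(config.seed)
    manifest: dict = {"seed": seed, "stages": {}, "hashes": {}}
    results: dict = {"config": config}

    def stage(name):
        manifest["stages"][name] = {"t0": time.perf_counter()}

    def done(name, **params):
        st = manifest["stages"][name]
        st["duration_s"] = round(time.perf_counter() - st.pop("t0"), 3)
        st.update(params)

    # --- BOLD simulation + factorization --------------------------------
    stage("simulate_bold")
    subjects, truth = synth.gen_bold_cohort(seed=seed, **config.bold)
    done("simulate_bold", **{k: v for k, v in config.bold.items()})
    manifest["hashes"]["bold"] = _hash(
        np.concatenate([s.values.ravel() for s in subjects]))

    stage("hmf")
    model = hmf_mod.HeterogeneousFactorization(
        subjects, config.bold["rank_shared"], config.bold["rank_specific"])
    fit = model.fit()
    _, meta_mse = fit.reconstruction_mse(mode="meta_only")
    done("hmf", mean_meta_mse=meta_mse, n_iter=len(fit.loss_trace),
         converged=fit.converged)
    manifest["hashes"]["shared_basis"] = _hash(fit.shared_basis)
    results["hmf"] = fit

    stage("fc")
    emap = connectome.EdgeIndexMap(subjects[0].n_regions)
    fc_edges = np.array([
        connectome.vectorize_upper(
            connectome.fisher_z(connectome.compute_fc(
                fit.reconstruct(s.subject_id, "meta_only"))), emap)
        for s in subjects])
    done("fc", n_edges=emap.n_edges)
    manifest["hashes"]["fc_edges"] = _hash(fc_edges)
    results["fc_edges"] = fc_edges

    # --- cohort simulation + shared/deviation patterns ------------------
    stage("cohort")
    cohort_cfg = resolve_cohort_config(config.cohort)
    cohort, clinical, ctruth = synth.gen_cohort_fc(seed=seed, **cohort_cfg)
    done("cohort", n_subjects=cohort.n_subjects)
    manifest["hashes"]["cohort"] = _hash(cohort.edges)

    stage("stacp")
    pls = stacp_mod.EdgePLS(cohort).fit()
    profs = pls.deviation_profiles()
    cosines = {
        f"{profs[a].disorder}|{profs[b].disorder}": stacp_mod.
        cosine_similarity(profs[a].vector, profs[b].vector)
        for a in range(len(profs)) for b in range(a + 1, len(profs))}
    done("stacp", recovery_cosine=float(
        stacp_mod.cosine_similarity(pls.direction.weights,
                                    ctruth.planted_direction)),
        dscd_cosines=cosines)
    manifest["hashes"]["stacp"] = _hash(pls.direction.weights)
    manifest["hashes"]["dscd"] = _hash(
        np.concatenate([p.vector for p in profs]))
    results["stacp"] = pls
    results["dscd"] = profs
    results["dscd_cosines"] = cosines
    results["clinical"] = clinical

    # --- molecular annotation -------------------------------------------
    stage("annotation")
    ann = dict(config.annotation)
    profiles_df, coords_df = synth.gen_spatial_profiles(
        ann["n_regions"], ann["n_variables"], seed=seed)
    profiles = tx.RegionProfileMatrix.from_frames(profiles_df, coords_df)
    emap_ann = connectome.EdgeIndexMap(ann["n_regions"])
    cge = tx.cge_matrix(profiles, normalize="none")
    dists = tx.pairwise_distances(profiles.coordinates)
    iu, ju = emap_ann.pairs
    decay = tx.fit_decay(cge[iu, ju], dists[iu, ju])
    contrib = tx.gene_contributions(profiles, emap_ann, normalize="none")
    # annotate a synthetic pattern living on the annotation parcellation
    pattern_rng = np.random.default_rng(seed)
    pattern = contrib.values @ \
        pattern_rng.standard_normal(ann["n_variables"]) \
        + 0.1 * pattern_rng.standard_normal(emap_ann.n_edges)
    gene_res = tx.pls_annotation(contrib, pattern, profiles.coordinates,
                                 n_perm=ann["n_perm"], n_boot=ann["n_boot"],
                                 seed=seed)
    feat_df = profiles_df.iloc[:, :ann["n_features"]]
    fprof = tx.RegionProfileMatrix.from_frames(feat_df, coords_df)
    cne = feat_mod.to_correlation(feat_mod.shrunk_covariance(fprof))
    fdecay = tx.fit_decay(cne[iu, ju], dists[iu, ju])
    scores = feat_mod.loo_feature_scores(fprof, fdecay)
    ncm = feat_mod.assemble_contributions(scores)
    feat_res = tx.pls_annotation(ncm, pattern, fprof.coordinates,
                                 n_perm=ann["n_perm"], n_boot=ann["n_boot"],
                                 max_components=ncm.values.shape[1],
                                 seed=seed)
    done("annotation", decay=(decay.amplitude, decay.offset, decay.scale),
         gene_perm_p=gene_res.permutation_p,
         feature_perm_p=feat_res.permutation_p)
    manifest["hashes"]["gene_weights"] = _hash(gene_res.variable_weights)
    manifest["hashes"]["feature_scores"] = _hash(scores.values)
    results["gene_annotation"] = gene_res
    results["feature_annotation"] = feat_res
    results["decay"] = decay

    # --- validation ------------------------------------------------------
    stage("validation")
    report = valid_mod.validate(cohort, seed=seed, **config.validation)
    done("validation", permutation_p=report.permutation_p,
         mean_auc=float(report.cv_auc.mean()))
    manifest["hashes"]["bootstrap_cosines"] = _hash(
        report.bootstrap_cosines)
    results["validation"] = report

    manifest["bundle_hash"] = hashlib.sha256(
        json.dumps(manifest["hashes"], sort_keys=True).encode()).hexdigest()
    results["manifest"] = manifest

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(manifest, out / "manifest.json")
        write_json({"stacp_weights": pls.direction.weights,
                    "dscd_cosines": cosines,
                    "permutation_p": report.permutation_p},
                   out / "results.json")
    return results
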