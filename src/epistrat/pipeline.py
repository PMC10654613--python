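"""End-to-end orchestration: simulate -> preprocess -> stratify -> survive
-> screen -> enrich -> validate -> sc-score, with a machine-readable run
manifest.

All randomness flows from a single top-level seed; each stage receives a
deterministically derived child seed so stages are reproducible in
isolation. Each stage writes plain-text outputs into the run directory and
records their SHA-256 digests in the manifest, so identical configuration
plus seed yields identical digests (timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .enrichment import (compare_alteration_frequencies, hypergeometric_overlap,
                         permutation_enrichment)
from .errors import ConfigurationError, DependencyError
from .nmf import (align_signatures, consensus_cluster, extract_top_genes,
                  label_clusters_by_outcome, nmf_factorize, select_rank)
from .preprocess import (filter_samples, normalize_log2, select_variable_epifactors,
                         size_factors)
from .scoring import classify_by_signatures
from .singlecell import assign_four_groups, module_score, one_vs_rest_de
from .survival import compare_clusters, meta_pcna, prognostic_screen
from .synthetic import (CohortConfig, generate_alterations, generate_cohort,
                        generate_single_cell)

log = logging.getLogger("epistrat")

ALL_STAGES = ("simulate", "preprocess", "stratify", "survive", "screen",
              "enrich", "validate", "sc-score")

_REQUIRES = {
    "preprocess": ("simulate",),
    "stratify": ("preprocess",),
    "survive": ("stratify",),
    "screen": ("preprocess",),
    "enrich": ("stratify",),
    "validate": ("stratify",),
    "sc-score": ("stratify", "survive"),
}


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    config: dict[str, Any] = {
        "seed": 0,
        "stages": list(ALL_STAGES),
        "cohort": {},
        "preprocess": {"purity_threshold": 0.70, "min_cohort": 70,
                       "target_range": [500, 600]},
        "nmf": {"ranks": [2, 3, 4], "n_runs": 30, "max_iter": 300, "tol": 1e-5},
        "screen": {"adjust_for": ["age", "sex"], "alpha": 0.05,
                   "endpoint": "pfi", "with_meta_pcna": True},
        "enrich": {"n_perm": 10000},
        "single_cell": {"n_cells": 600, "group_fracs": [0.25, 0.25, 0.25, 0.25],
                        "n_bins": 24, "n_ctrl": 100},
    }
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in loaded.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    unknown = set(config["stages"]) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    return config


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the requested stages and return the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config["stages"])
    for stage in stages:
        for need in _REQUIRES.get(stage, ()):
            if need not in stages:
                raise DependencyError(
                    f"stage {stage!r} needs output of stage {need!r}, "
                    f"which is not scheduled")

    seed = int(config["seed"])
    manifest: dict[str, Any] = {"config": config, "seed": seed,
                                "stage_seeds": {}, "outputs": {},
                                "timestamps": {}}
    ctx: dict[str, Any] = {}

    def record(stage: str, **files: Path) -> None:
        manifest["outputs"][stage] = {name: _digest(p) for name, p in files.items()}
        manifest["timestamps"][stage] = time.time()

    for stage in stages:
        sseed = _stage_seed(seed, stage)
        manifest["stage_seeds"][stage] = sseed
        log.info("stage %s (seed %d)", stage, sseed)
        _RUNNERS[stage](config, ctx, outdir, sseed, record)

    eio.write_json({k: v for k, v in manifest.items() if k != "timestamps"},
                   outdir / "manifest.json")
    manifest["outputs"]["manifest"] = {"manifest.json": _digest(outdir / "manifest.json")}
    return manifest


# ---------------------------------------------------------------------------
# stage runners


def _run_simulate(config, ctx, outdir, seed, record):
    cohort_cfg = CohortConfig(**{**config["cohort"], "seed": seed})
    counts, clinical, annotation, truth = generate_cohort(cohort_cfg)
    ctx.update(cohort_cfg=cohort_cfg, counts=counts, clinical=clinical,
               annotation=annotation, truth=truth)
    eio.write_counts_tsv(counts, outdir / "counts.tsv")
    eio.write_table(clinical, outdir / "clinical.tsv", index=False)
    eio.write_table(annotation, outdir / "annotation.tsv", index=False)
    eio.write_table(truth.sample_program.to_frame(), outdir / "truth_samples.tsv")
    eio.write_table(truth.gene_role.to_frame(), outdir / "truth_genes.tsv")
    eio.write_json({"cohort_config": dataclasses.asdict(cohort_cfg)},
                   outdir / "cohort_config.json")
    record("simulate", counts=outdir / "counts.tsv",
           clinical=outdir / "clinical.tsv",
           annotation=outdir / "annotation.tsv")


def _run_preprocess(config, ctx, outdir, seed, record):
    _need(ctx, "counts", "simulate")
    p = config["preprocess"]
    kept, undersized = filter_samples(ctx["clinical"], p["purity_threshold"],
                                      p["min_cohort"])
    counts = ctx["counts"][kept]
    factors = size_factors(counts)
    norm = normalize_log2(counts, factors)
    selection = select_variable_epifactors(norm, ctx["annotation"],
                                           tuple(p["target_range"]))
    ctx.update(kept_samples=kept, norm=norm, selection=selection,
               clinical_kept=ctx["clinical"].loc[kept])
    eio.write_table(selection.sds.loc[selection.genes].rename("sd").to_frame(),
                    outdir / "variable_epifactors.tsv")
    eio.write_json({"n_kept": len(kept), "undersized": undersized,
                    "sd_cutoff": selection.cutoff,
                    "n_selected": len(selection.genes),
                    "in_target": selection.in_target},
                   outdir / "preprocess.json")
    record("preprocess", selected=outdir / "variable_epifactors.tsv",
           summary=outdir / "preprocess.json")


def _run_stratify(config, ctx, outdir, seed, record):
    _need(ctx, "norm", "preprocess")
    p = config["nmf"]
    V = ctx["norm"].loc[ctx["selection"].genes]
    metrics = {}
    results = {}
    for k in p["ranks"]:
        res = consensus_cluster(V, k, n_runs=p["n_runs"], seed=seed,
                                max_iter=p["max_iter"], tol=p["tol"])
        results[k] = res
        metrics[k] = res.metrics
    chosen = select_rank(metrics)
    best = results[chosen]
    fit = nmf_factorize(V.to_numpy(), chosen, seed=seed,
                        max_iter=p["max_iter"], tol=p["tol"])
    signatures = align_signatures(extract_top_genes(fit.W, list(V.index)),
                                  fit.H, best.labels)
    outcome, flagged = (None, True)
    if chosen == 2:
        outcome, flagged = label_clusters_by_outcome(best.labels,
                                                     ctx["clinical_kept"])
        signatures.outcome_labels = outcome
    ctx.update(consensus=best, labels=best.labels, signatures=signatures,
               chosen_rank=chosen, metric_table=metrics, V=V)
    eio.write_table(best.consensus, outdir / "consensus.tsv")
    labels_out = best.labels.to_frame()
    labels_out["outcome"] = [outcome.get(c, "") if outcome else ""
                             for c in best.labels]
    eio.write_table(labels_out, outdir / "labels.tsv")
    eio.write_json({"metrics": {str(k): v for k, v in metrics.items()},
                    "chosen_rank": chosen, "outcome_unlabeled": flagged},
                   outdir / "rank_selection.json")
    gmt = {f"cluster_{c}" + (f"_{outcome[c]}" if outcome else ""): genes
           for c, genes in signatures.genes.items()}
    eio.write_gmt(gmt, outdir / "signatures.gmt")
    eio.write_table(signatures.scores.rename("kim_park_score").to_frame(),
                    outdir / "signature_scores.tsv")
    record("stratify", labels=outdir / "labels.tsv",
           signatures=outdir / "signatures.gmt",
           metrics=outdir / "rank_selection.json")


def _run_survive(config, ctx, outdir, seed, record):
    _need(ctx, "labels", "stratify")
    out = compare_clusters(ctx["labels"], ctx["clinical_kept"])
    payload = {}
    for endpoint, res in out.items():
        payload[endpoint] = {
            "logrank": res["logrank"],
            "cox_cluster_p": res["cox"].p("cluster"),
            "cox_cluster_hr": float(res["cox"].params.loc["cluster", "hr"]),
            "flags": res["flags"],
        }
    ctx["cluster_comparison"] = out
    eio.write_json(payload, outdir / "cluster_survival.json")
    record("survive", results=outdir / "cluster_survival.json")


def _run_screen(config, ctx, outdir, seed, record):
    _need(ctx, "norm", "preprocess")
    p = config["screen"]
    adjust = list(p["adjust_for"])
    clinical = ctx["clinical_kept"].copy()
    if p.get("with_meta_pcna", False):
        sig, score = meta_pcna(ctx["norm"])
        clinical["meta_pcna_score"] = score.loc[clinical.index]
        adjust = adjust + ["meta_pcna_score"]
        ctx["meta_pcna_signature"] = sig
        eio.write_table(pd.DataFrame({"gene": sig}), outdir / "meta_pcna.tsv",
                        index=False)
    table = prognostic_screen(ctx["norm"], clinical, ctx["selection"].genes,
                              adjust_for=adjust, alpha=p["alpha"],
                              endpoint=p["endpoint"])
    ctx["prognostic_table"] = table
    eio.write_table(table, outdir / "prognostic_screen.tsv")
    record("screen", table=outdir / "prognostic_screen.tsv")


def _run_enrich(config, ctx, outdir, seed, record):
    _need(ctx, "signatures", "stratify")
    universe = pd.Index(ctx["selection"].genes)
    top = set().union(*ctx["signatures"].genes.values())
    flags = pd.Series(universe.isin(top), index=universe)
    membership = {}
    ann = ctx["annotation"]
    for gene, row in ann[ann["is_epifactor"].astype(bool)].iterrows():
        for cplx in str(row["complexes"]).split(";"):
            if cplx:
                membership.setdefault(cplx, []).append(gene)
    table = permutation_enrichment(flags, membership,
                                   n_perm=config["enrich"]["n_perm"], seed=seed)
    ctx["complex_enrichment"] = table
    eio.write_table(table, outdir / "complex_enrichment.tsv")
    # alteration comparison on simulated binary tables for a gene panel
    rng = np.random.default_rng(seed)
    panel = list(rng.choice(ctx["counts"].index.to_numpy(), size=40, replace=False))
    freqs = {g: (float(rng.uniform(0.0, 0.4)), float(rng.uniform(0.0, 0.4)))
             for g in panel}
    alterations = generate_alterations(ctx["cohort_cfg"], freqs)
    alt_table = compare_alteration_frequencies(
        alterations[ctx["labels"].index], ctx["labels"])
    ctx["alteration_table"] = alt_table
    eio.write_table(alt_table, outdir / "alteration_comparison.tsv")
    eio.write_json({"seed": seed, "n_perm": config["enrich"]["n_perm"]},
                   outdir / "enrich_manifest.json")
    record("enrich", complexes=outdir / "complex_enrichment.tsv",
           alterations=outdir / "alteration_comparison.tsv")


def _run_validate(config, ctx, outdir, seed, record):
    _need(ctx, "signatures", "stratify")
    counts, clinical, _, truth = generate_cohort(ctx["cohort_cfg"], replicate=1)
    norm = normalize_log2(counts, size_factors(counts))
    sigs = ctx["signatures"]
    outcome = sigs.outcome_labels or {1: "poor", 2: "better"}
    poor = next(c for c, lab in outcome.items() if lab == "poor")
    better = next(c for c, lab in outcome.items() if lab == "better")
    if not sigs.genes[poor] or not sigs.genes[better]:
        eio.write_json({"skipped": "empty_signature"},
                       outdir / "validation_summary.json")
        record("validate", summary=outdir / "validation_summary.json")
        return
    calls = classify_by_signatures(norm, sigs.genes[poor], sigs.genes[better])
    ctx["validation_calls"] = calls
    ctx["validation_truth"] = truth
    eio.write_table(calls, outdir / "validation_calls.tsv")
    # overlap of the learned poor signature with the planted poor-program
    # signature of the held-out cohort (universe = variable genes)
    planted_poor = truth.signature_genes(2)
    universe = set(ctx["selection"].genes)
    overlap_p = hypergeometric_overlap(
        set(sigs.genes[poor]) & universe, set(planted_poor) & universe,
        len(universe))
    eio.write_json({"n_poor": int((calls["call"] == "poor").sum()),
                    "n_better": int((calls["call"] == "better").sum()),
                    "poor_signature_overlap_p": overlap_p},
                   outdir / "validation_summary.json")
    record("validate", calls=outdir / "validation_calls.tsv")


def _run_sc_score(config, ctx, outdir, seed, record):
    _need(ctx, "signatures", "stratify")
    p = config["single_cell"]
    cells, truth = generate_single_cell(ctx["cohort_cfg"], p["n_cells"],
                                        tuple(p["group_fracs"]))
    sigs = ctx["signatures"]
    outcome = sigs.outcome_labels or {1: "poor", 2: "better"}
    poor = next(c for c, lab in outcome.items() if lab == "poor")
    better = next(c for c, lab in outcome.items() if lab == "better")
    if not sigs.genes[poor] or not sigs.genes[better]:
        eio.write_json({"skipped": "empty_signature"}, outdir / "cell_groups.json")
        record("sc-score", groups=outdir / "cell_groups.json")
        return
    score_poor = module_score(cells, sigs.genes[poor], p["n_bins"], p["n_ctrl"],
                              seed=seed)
    score_better = module_score(cells, sigs.genes[better], p["n_bins"],
                                p["n_ctrl"], seed=seed + 1)
    groups = assign_four_groups(score_poor, score_better)
    de = one_vs_rest_de(cells, groups["group"],
                        genes=sigs.genes[poor] + sigs.genes[better])
    ctx.update(sc_groups=groups, sc_truth=truth, sc_de=de)
    eio.write_table(groups, outdir / "cell_groups.tsv")
    eio.write_table(de, outdir / "cell_de.tsv", index=False)
    record("sc-score", groups=outdir / "cell_groups.tsv",
           de=outdir / "cell_de.tsv")


def _need(ctx: dict, key: str, producer: str) -> None:
    if key not in ctx:
        raise DependencyError(f"missing input {key!r}: run stage {producer!r} first")


_RUNNERS = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "stratify": _run_stratify,
    "survive": _run_survive,
    "screen": _run_screen,
    "enrich": _run_enrich,
    "validate": _run_validate,
    "sc-score": _run_sc_score,
}
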