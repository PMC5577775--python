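"""End-to-end orchestration: GLCPs -> synteny -> nulls -> sequence -> features.

A pipeline run is a pure function of (inputs, config, seed): every stage
derives its seed from the global one, and every run writes a provenance
block (config hash, seeds, package version) next to its report tables.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import numpy as np
import yaml

from . import __version__
from .feature_stats import expression_correlation, tau_table
from .glcp_caller import call_glcps, default_criteria, sample_family_matched, write_glcp_table
from .null_models import (
    SCHEMES,
    empirical_null,
    estimate_fdr,
    make_synteny_count_fn,
    write_null_table,
)
from .seq_similarity import pairwise_similarity_fdr
from .synteny import (
    SyntenyParams,
    call_syntenic_pairs,
    ortholog_recovery,
    scaled_max_distance,
    write_pair_table,
)
from .synthetic_data import ScenarioConfig, generate_scenario, write_scenario


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def candidate_gene_ids(annotation) -> list[str]:
    return sorted(
        g.gene_id
        for g in annotation.genes.values()
        if g.biotype in ("lncRNA", "unprocessed_pseudogene")
    )


def synteny_params_for(anno_q, anno_t) -> SyntenyParams:
    return SyntenyParams(
        max_dist_q=scaled_max_distance(anno_q.genome_size, anno_t.genome_size),
        max_dist_t=scaled_max_distance(anno_t.genome_size, anno_t.genome_size),
    )


def run_pipeline(config: dict, out_dir: str) -> dict:
    """Run every stage on a simulated scenario described by ``config``.

    Config keys: ``seed`` (int, required), ``scenario`` (ScenarioConfig
    overrides), ``null_iterations`` (per-scheme dict or int; 0 disables),
    ``seqsim`` (dict: k_random, shuffles, thresholds; absent disables),
    ``recovery`` (bool).  Writes TSV reports plus provenance.json.
    """
    os.makedirs(out_dir, exist_ok=True)
    seed = int(config["seed"])
    scen_cfg = ScenarioConfig(seed=derive_seed(seed, "scenario"), **config.get("scenario", {}))
    scenario = generate_scenario(scen_cfg)
    write_scenario(scenario, os.path.join(out_dir, "scenario"), force=True)

    results: dict = {"scenario": scenario}
    anno_q, anno_t = scenario.anno_ref, scenario.anno_target
    homology = scenario.homology

    # stage 1: GLCP calling
    criteria = default_criteria(anno_q.species, homology.roster)
    calls = call_glcps(homology, anno_q.species, criteria)
    glcp_ids = sorted({c.gene_id for c in calls} & set(anno_q.genes))
    write_glcp_table(calls, os.path.join(out_dir, "glcps.tsv"))
    results["glcps"] = glcp_ids

    # stage 2: synteny
    params = synteny_params_for(anno_q, anno_t)
    candidates = candidate_gene_ids(anno_t)
    pairs = call_syntenic_pairs(
        glcp_ids, candidates, anno_q, anno_t, homology, scenario.chains, params
    )
    write_pair_table(pairs, os.path.join(out_dir, "pairs.tsv"))
    syntenic = [p for p in pairs if p.verdict == "syntenic"]
    results["pairs"] = pairs
    results["syntenic"] = syntenic

    # pooled report: one row per candidate with supporting-species count
    support: dict[str, set[str]] = {}
    for p in syntenic:
        support.setdefault(p.target_gene, set()).add(p.query_species)
    with open(os.path.join(out_dir, "pooled.tsv"), "w") as fh:
        fh.write("candidate\tbiotype\tn_reference_species\tge2_species\n")
        for cand in sorted(support):
            n = len(support[cand])
            fh.write(f"{cand}\t{anno_t.genes[cand].biotype}\t{n}\t{int(n >= 2)}\n")

    if config.get("recovery", False):
        rec = ortholog_recovery(
            anno_q, anno_t, homology, scenario.chains, params,
            seed=derive_seed(seed, "recovery"),
        )
        results["recovery"] = rec

    # stage 3: randomization nulls
    null_iters = config.get("null_iterations", 0)
    if null_iters:
        if isinstance(null_iters, int):
            null_iters = {s: null_iters for s in SCHEMES}
        null_results = []
        for scheme in SCHEMES:
            n_iter = null_iters.get(scheme, 0)
            if not n_iter:
                continue
            fn = make_synteny_count_fn(
                glcp_ids, candidates, anno_q, anno_t, homology,
                scenario.chains, params, scheme,
            )
            null_results.append(
                empirical_null(fn, scheme, n_iter, derive_seed(seed, f"null:{scheme}"))
            )
        write_null_table(null_results, os.path.join(out_dir, "nulls.tsv"))
        results["nulls"] = {r.scheme: r for r in null_results}

    # stage 4: sequence similarity with random-GLCP FDR
    seqsim_cfg = config.get("seqsim")
    if seqsim_cfg is not None:
        seqs = scenario.sequences
        truth_by_derived = {t.derived_gene: t.glcp_gene for t in scenario.truth}
        real_pairs = [
            (truth_by_derived.get(p.target_gene, p.query_gene), p.target_gene)
            for p in syntenic
            if p.target_gene in seqs and p.query_gene in seqs
        ]
        real_pairs = [(q, t) for q, t in real_pairs if q in seqs]
        pool = [g for g in scenario.glcps if g in seqs]
        if real_pairs and len(pool) > 1:
            sim = pairwise_similarity_fdr(
                real_pairs,
                seqs,
                pool,
                thresholds=seqsim_cfg.get("thresholds", [0.01, 0.05]),
                k=seqsim_cfg.get("k_random", 10),
                n_shuffles=seqsim_cfg.get("shuffles", 100),
                seed=derive_seed(seed, "seqsim"),
            )
            results["seqsim"] = sim
            with open(os.path.join(out_dir, "seqsim_fdr.tsv"), "w") as fh:
                fh.write("threshold\tfdr\n")
                for t, v in sim["fdr"].items():
                    fh.write(f"{t}\t{v}\n")

    # stage 5: feature statistics
    glcp_tau = tau_table(scenario.expr_ref, glcp_ids)
    matched = sample_family_matched(glcp_ids, homology, derive_seed(seed, "matched"))
    matched = [g for g in matched if g in scenario.expr_ref]
    other_tau = tau_table(scenario.expr_ref, matched)
    corr = expression_correlation(
        [(t.glcp_gene, t.derived_gene) for t in scenario.truth],
        scenario.expr_ref,
        scenario.expr_target,
    )
    results["tau_glcp_mean"] = float(np.nanmean(list(glcp_tau.values()))) if glcp_tau else float("nan")
    results["tau_matched_mean"] = float(np.nanmean(list(other_tau.values()))) if other_tau else float("nan")
    results["expression_correlation"] = corr
    with open(os.path.join(out_dir, "features.tsv"), "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"tau_glcp_mean\t{results['tau_glcp_mean']:.4f}\n")
        fh.write(f"tau_matched_mean\t{results['tau_matched_mean']:.4f}\n")
        fh.write(f"expression_spearman_rho\t{corr[0]:.4f}\n")
        fh.write(f"expression_spearman_p\t{corr[1]:.4g}\n")

    provenance = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "scenario_config": asdict(scen_cfg),
        "stage_seeds": {
            s: derive_seed(seed, s)
            for s in ("scenario", "recovery", "matched", "seqsim")
        },
    }
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return results
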