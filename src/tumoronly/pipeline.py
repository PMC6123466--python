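"""End-to-end orchestration: simulate, QC, filter, hotspots, associations,
survival screens, and a run manifest with telescoping stage counts.

Stage outputs are files, so each CLI subcommand is independently runnable.
All outputs are deterministic given the seed: two runs from the same
configuration agree byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (attach_q, build_mutation_matrix, pairwise_cooccurrence,
                    results_frame, test_categorical_association,
                    vaf_germline_suspicion)
from .config import RunConfig
from .errors import DegenerateInputError, PipelineError
from .filters import (burden_summary, get_policy, run_filter_cascade,
                      sample_coverage_qc, write_knowledge_base,
                      KnowledgeBaseSite)
from .hotspots import find_hotspots, gene_recurrence_table, hotspot_results_frame
from .io import write_maf
from .prognosis import (PermutationPlan, multivariate_screen,
                        permutation_adjust, screen_results_frame,
                        survival_frame, two_gene_analysis, univariate_screen)
from .synth import CohortGenerator, GeneratorConfig, GeneSpec, default_genes


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(size: str = "tiny", seed: int = 11) -> GeneratorConfig:
    """Bundled test cohorts: ``tiny`` (12 samples, 3 genes, hand-checkable)
    and ``small`` (400 samples, 20 genes, for statistical tests)."""
    if size == "tiny":
        genes = [
            GeneSpec("PIK3CA", somatic_rate=0.5, reference_freq=0.3,
                     hotspot_position=1047, hotspot_weight=0.5,
                     protein_length=1068, log_hr={"BCSS": -0.3}),
            GeneSpec("TP53", somatic_rate=0.3, reference_freq=0.25,
                     protein_length=393, log_hr={"BCSS": 0.5}),
            GeneSpec("MAP3K1", somatic_rate=0.3, reference_freq=0.08,
                     protein_length=1512, log_hr={"BCSS": -0.4},
                     class_mix={"missense": 0.4, "nonsense": 0.3,
                                "frameshift": 0.3}),
        ]
        return GeneratorConfig(n_samples=12, genes=genes, germline_rate=1.0,
                               artifact_rate=2.0, n_germline_pool=6,
                               endpoints=("BCSS",), seed=seed)
    if size == "small":
        genes = list(default_genes())
        # a splice-junction hotspot present in the study but essentially
        # absent from the reference catalog — a discoverable novel hotspot
        genes.append(GeneSpec(
            "CBFB", somatic_rate=0.04, reference_freq=0.003,
            protein_length=182, hotspot_position=2, hotspot_weight=0.85,
            class_mix={"splice_site": 0.70, "missense": 0.20,
                       "nonsense": 0.10}))
        extra = ["ERBB2", "ERBB3", "PIK3R1", "RB1", "ARID1A",
                 "XBP1", "AKT1", "RUNX1", "FOXA1"]
        for i, name in enumerate(extra):
            genes.append(GeneSpec(name, somatic_rate=0.02 + 0.005 * (i % 4),
                                  reference_freq=0.02, protein_length=600))
        return GeneratorConfig(n_samples=400, genes=genes, seed=seed)
    raise PipelineError("fixtures", f"unknown fixture size {size!r}")


def default_knowledge_base(config: GeneratorConfig) -> list[KnowledgeBaseSite]:
    """Knowledge-base sites at the configured hotspot positions."""
    sites = []
    for g in config.genes:
        if g.hotspot_position is not None:
            pos = g.start + 3 * (g.hotspot_position - 1)
            sites.append(KnowledgeBaseSite(
                chrom=g.chrom, pos=pos, ref="A", alt="G", gene=g.name,
                protein_change=f"X{g.hotspot_position}X",
                source="synthetic-curation"))
    return sites


def run_all(config: RunConfig, outdir: str | Path,
            gen_config: GeneratorConfig | None = None) -> dict:
    """Run the full synthetic-cohort pipeline and write all outputs.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if gen_config is None:
        gen_config = make_fixtures("small", seed=config.seed)
    else:
        gen_config = dataclasses.replace(gen_config, seed=config.seed)

    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "inputs": {}}

    # -- simulate -----------------------------------------------------------
    gen = CohortGenerator(gen_config)
    cohort = gen.generate_cohort()
    panels = gen.generate_reference_panels()
    multistudy = gen.generate_multistudy_maf()
    kb = default_knowledge_base(gen_config)

    inputs_dir = outdir / "inputs"
    cohort.write(inputs_dir)
    panels.to_dir(inputs_dir / "panels")
    multistudy.to_tsv(inputs_dir / "multistudy.maf.tsv")
    write_knowledge_base(kb, inputs_dir / "knowledge_base.tsv")
    gen_config.dump(inputs_dir / "generator_config.yaml")
    config.dump(outdir / "resolved_config.yaml")
    manifest["config_hash"] = _sha256(outdir / "resolved_config.yaml")
    for f in sorted(inputs_dir.rglob("*")):
        if f.is_file():
            manifest["inputs"][str(f.relative_to(outdir))] = _sha256(f)

    # -- sample QC ----------------------------------------------------------
    qc = sample_coverage_qc(cohort.coverage_fraction, config.thresholds)
    passing = sorted(s for s, ok in qc.items() if ok)
    manifest["stages"]["qc"] = {
        "samples_in": len(qc), "samples_out": len(passing),
        "failed": sorted(s for s, ok in qc.items() if not ok)}

    variants = [v for v in cohort.variants if qc[v.sample_id]]

    # -- filter cascade -----------------------------------------------------
    retained, trace, summary = run_filter_cascade(
        variants, panels, kb, config.thresholds, regions=cohort.regions)
    write_maf(retained, outdir / "filtered.maf")
    trace.to_csv(outdir / "filter_trace.tsv", sep="\t", index=False,
                 lineterminator="\n")
    (outdir / "filter_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))

    chain = [("input", summary["input"]), ("on_target", summary["on_target"])]
    running = summary["on_target"]
    for stage, removed in summary["stage_removal_counts"].items():
        running -= removed
        chain.append((stage, running))
    chain.append(("with_rescue", summary["retained"]))
    manifest["stages"]["filter"] = {"counts": chain,
                                    "rescued": summary["rescued"]}

    # -- mutation burden ----------------------------------------------------
    tiled = sum(r.length for r in cohort.regions)
    policy_ns = get_policy("non_silent", config.rna_whitelist)
    ns_variants = [v for v in retained if policy_ns.includes(v)]
    counts = {s: 0 for s in passing}
    for v in ns_variants:
        counts[v.sample_id] += 1
    burden = burden_summary(counts, tiled,
                            correction=cohort.truth.mpmb_correction)
    (outdir / "mutation_burden.json").write_text(
        json.dumps({k: v for k, v in burden.items() if k != "per_sample"},
                   indent=1, sort_keys=True))

    # -- recurrence & hotspots ----------------------------------------------
    recurrence = gene_recurrence_table(retained, policy_ns, len(passing))
    recurrence.to_csv(outdir / "gene_recurrence.tsv", sep="\t", index=False,
                      lineterminator="\n")
    hotspots = find_hotspots(ns_variants, multistudy, n_study=len(passing),
                             novel_q=config.hotspot_q)
    hotspot_results_frame(hotspots).to_csv(
        outdir / "hotspots.tsv", sep="\t", index=False, lineterminator="\n",
        float_format="%.6g")
    manifest["stages"]["hotspots"] = {
        "positions_tested": len(hotspots),
        "novel": sum(1 for h in hotspots if h.novel)}

    # -- associations -------------------------------------------------------
    clinical = [c for c in cohort.clinical if c.sample_id in set(passing)]
    subtype = {c.sample_id: c.subtype for c in clinical}
    assoc_results = []
    for policy_name in config.policies:
        policy = get_policy(policy_name, config.rna_whitelist)
        matrix = build_mutation_matrix(retained, passing, policy)
        labels = np.array([subtype[s] for s in passing])
        known = labels != "unknown"
        family = []
        for gene in matrix.genes:
            carrier = matrix.carriers(gene)[known]
            if carrier.sum() == 0:
                continue
            try:
                r = test_categorical_association(
                    carrier, labels[known], gene=gene, policy=policy_name,
                    covariate="subtype")
            except DegenerateInputError:
                continue
            family.append(r)
        attach_q(family)
        assoc_results.extend(family)
    if assoc_results:
        results_frame(assoc_results, config.reportable_q).to_csv(
            outdir / "subtype_associations.tsv", sep="\t", index=False,
            lineterminator="\n", float_format="%.6g")

    matrix_ns = build_mutation_matrix(retained, passing, policy_ns)
    cooc = pairwise_cooccurrence(matrix_ns, top_k=config.top_k_cooccurrence)
    results_frame(cooc, config.reportable_q).to_csv(
        outdir / "cooccurrence.tsv", sep="\t", index=False,
        lineterminator="\n", float_format="%.6g")

    suspicion = vaf_germline_suspicion(
        ns_variants,
        flagged_genes=tuple(g for g in ("BRCA1", "BRCA2", "ATM")
                            if any(v.gene == g for v in ns_variants)) or
        ("ATM",))
    (outdir / "vaf_germline_suspicion.json").write_text(
        json.dumps(suspicion, indent=1, sort_keys=True))
    manifest["stages"]["associations"] = {
        "subtype_tests": len(assoc_results), "cooccurrence_pairs": len(cooc)}

    # -- survival screens ---------------------------------------------------
    screens_frames = []
    screen_counts = {}
    available = {r.endpoint for r in cohort.survival}
    endpoints = [e for e in config.endpoints if e in available]
    for endpoint in endpoints:
        surv = survival_frame(cohort.survival, endpoint, passing)
        for policy_name in config.policies:
            policy = get_policy(policy_name, config.rna_whitelist)
            matrix = build_mutation_matrix(retained, passing, policy)
            uni = univariate_screen(matrix, surv, endpoint, ties=config.ties)
            multi = multivariate_screen(matrix, surv, clinical, endpoint,
                                        split_at=config.split_at,
                                        ties=config.ties)
            plan = PermutationPlan(n_permutations=config.permutations,
                                   seed=config.seed,
                                   add_one=config.add_one_permutation_p)
            permutation_adjust(multi, matrix, surv, clinical, plan,
                               split_at=config.split_at, ties=config.ties)
            for label, results in (("univariate", uni),
                                   ("multivariate", multi)):
                df = screen_results_frame(results)
                df.insert(0, "model", label)
                screens_frames.append(df)
            screen_counts[f"{endpoint}:{policy_name}"] = {
                "genes": len(uni),
                "tested": sum(1 for r in uni if r.gate == "tested")}
    screens = pd.concat(screens_frames, ignore_index=True)
    screens.to_csv(outdir / "survival_screens.tsv", sep="\t", index=False,
                   lineterminator="\n", float_format="%.6g")
    manifest["stages"]["survival"] = screen_counts

    # -- two-gene interaction ----------------------------------------------
    try:
        surv = survival_frame(cohort.survival, endpoints[0], passing)
        tg = two_gene_analysis(matrix_ns, surv)
        (outdir / "two_gene_analysis.json").write_text(json.dumps(
            {"group_sizes": tg["group_sizes"], "chi2": tg["chi2"],
             "df": tg["df"], "p": tg["p"]}, indent=1, sort_keys=True))
        manifest["stages"]["two_gene"] = tg["group_sizes"]
    except DegenerateInputError as exc:
        manifest["stages"]["two_gene"] = {"skipped": str(exc)}

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
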