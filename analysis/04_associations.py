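#!/usr/bin/env python
"""Mutation-covariate associations on the filtered cohort.

Per class policy (non-silent, truncating): carrier-vs-subtype tests
(Fisher/chi-squared as appropriate, BH per family), co-occurrence among the
top seven most-mutated genes, and the VAF-based germline-suspicion report.

Reads results/cohort/ and results/filtered/; writes results/associations/.
"""

import json
from pathlib import Path

import numpy as np

from tumoronly.assoc import (attach_q, build_mutation_matrix,
                             pairwise_cooccurrence, results_frame,
                             test_categorical_association,
                             vaf_germline_suspicion)
from tumoronly.errors import DegenerateInputError
from tumoronly.filters import get_policy
from tumoronly.io import read_clinical, read_maf

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "associations"


def main() -> None:
    variants = read_maf(ROOT / "filtered" / "filtered.maf")
    clinical = read_clinical(ROOT / "cohort" / "clinical.tsv")
    present = {v.sample_id for v in variants}
    clinical = [c for c in clinical
                if c.sample_id in present or True]  # keep all-false rows
    samples = [c.sample_id for c in clinical]
    subtype = np.array([c.subtype for c in clinical])
    OUT.mkdir(parents=True, exist_ok=True)

    all_results = []
    for policy_name in ("non_silent", "fs_ns"):
        policy = get_policy(policy_name)
        matrix = build_mutation_matrix(variants, samples, policy)
        family = []
        for gene in matrix.genes:
            carrier = matrix.carriers(gene)
            if carrier.sum() == 0:
                continue
            try:
                family.append(test_categorical_association(
                    carrier, subtype, gene=gene, policy=policy_name,
                    covariate="subtype"))
            except DegenerateInputError:
                continue
        attach_q(family)
        all_results.extend(family)
    df = results_frame(all_results)
    df.to_csv(OUT / "subtype_associations.tsv", sep="\t", index=False,
              lineterminator="\n", float_format="%.6g")
    reportable = df[df["reportable"]]
    print(f"{len(df)} gene x subtype tests; "
          f"{len(reportable)} reportable at q < 0.2:")
    for row in reportable.itertuples(index=False):
        print(f"  {row.gene} [{row.policy}] p = {row.p:.2g}, q = {row.q:.2g}")

    matrix = build_mutation_matrix(variants, samples,
                                   get_policy("non_silent"))
    cooc = pairwise_cooccurrence(matrix, top_k=7)
    cdf = results_frame(cooc)
    cdf.to_csv(OUT / "cooccurrence.tsv", sep="\t", index=False,
               lineterminator="\n", float_format="%.6g")
    hits = cdf[cdf["q"] < 0.2]
    print(f"{len(cdf)} gene pairs tested; significant at q < 0.2:")
    for row in hits.itertuples(index=False):
        print(f"  {row.gene}: {row.direction} (q = {row.q:.2g})")

    suspicion = vaf_germline_suspicion(
        variants, flagged_genes=tuple(
            g for g in ("BRCA1", "BRCA2", "ATM")
            if any(v.gene == g for v in variants)) or ("ATM",))
    (OUT / "vaf_germline_suspicion.json").write_text(
        json.dumps(suspicion, indent=1, sort_keys=True))
    print(f"mean VAF flagged genes {suspicion['mean_vaf_flagged']:.3f} vs "
          f"other {suspicion['mean_vaf_other']:.3f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
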