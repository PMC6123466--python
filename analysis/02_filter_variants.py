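#!/usr/bin/env python
"""Run the tumor-only somatic filtering cascade on the simulated cohort.

Applies sample coverage QC, then the six-stage cascade (target restriction,
population MAF > 0.1%, >= 10/151 unmatched-normal calls, exome and genome
read-count panels, binomial LLR classifier) with knowledge-base rescue, and
scores the verdicts against the generator's truth labels.

Reads results/cohort/; writes results/filtered/ (filtered MAF, per-variant
trace, summary, truth confusion table).
"""

import json
from pathlib import Path

from tumoronly.config import FilterThresholds
from tumoronly.filters import (ReferencePanels, read_knowledge_base,
                               run_filter_cascade, sample_coverage_qc)
from tumoronly.io import read_bed, read_maf, write_maf
from tumoronly.synth import CohortTruth

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "filtered"


def main() -> None:
    cohort_dir = ROOT / "cohort"
    variants = read_maf(cohort_dir / "variants.maf")
    panels = ReferencePanels.from_dir(cohort_dir / "panels")
    kb = read_knowledge_base(cohort_dir / "knowledge_base.tsv")
    regions = read_bed(cohort_dir / "targets.bed")
    truth = CohortTruth.from_json(cohort_dir / "truth.json")
    thresholds = FilterThresholds()

    coverage = {}
    for line in (cohort_dir / "coverage.tsv").read_text().splitlines()[1:]:
        sample, frac = line.split("\t")
        coverage[sample] = float(frac)
    qc = sample_coverage_qc(coverage, thresholds)
    passing = {s for s, ok in qc.items() if ok}
    variants = [v for v in variants if v.sample_id in passing]
    print(f"QC: {len(passing)} of {len(qc)} samples pass "
          f"(>= 80% of bases over 20x)")

    retained, trace, summary = run_filter_cascade(
        variants, panels, kb, thresholds, regions=regions)
    OUT.mkdir(parents=True, exist_ok=True)
    write_maf(retained, OUT / "filtered.maf")
    trace.to_csv(OUT / "filter_trace.tsv", sep="\t", index=False,
                 lineterminator="\n")

    confusion = {"somatic": {"kept": 0, "removed": 0},
                 "germline": {"kept": 0, "removed": 0},
                 "artifact": {"kept": 0, "removed": 0}}
    kept = {(v.sample_id, v.key) for v in retained}
    for v in variants:
        label = truth.label_of(v)
        confusion[label]["kept" if (v.sample_id, v.key) in kept
                         else "removed"] += 1
    summary["truth_confusion"] = confusion
    (OUT / "filter_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))

    som = confusion["somatic"]
    germ = confusion["germline"]
    art = confusion["artifact"]
    print(f"cascade: {summary['retained']} of {summary['input']} retained "
          f"({summary['rescued']} rescued)")
    print(f"  somatic sensitivity  {som['kept']}/{som['kept'] + som['removed']}")
    print(f"  germline removed     {germ['removed']}/{germ['kept'] + germ['removed']}")
    print(f"  artifacts removed    {art['removed']}/{art['kept'] + art['removed']}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
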