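#!/usr/bin/env python
"""Simulate the study cohort.

Generates a 400-patient, 20-gene targeted-capture tumor-only cohort with
reference panels (population frequencies, 151 unmatched-normal calls,
912-exome and 87-genome read-count panels), a 1000-sample multi-study
reference MAF, and ground-truth labels, then reports the truth composition.

Writes results/cohort/ (variant MAF, clinical and survival TSVs, panels,
truth JSON) for the downstream steps.
"""

from collections import Counter
from pathlib import Path

from tumoronly.pipeline import default_knowledge_base, make_fixtures
from tumoronly.filters import write_knowledge_base
from tumoronly.synth import CohortGenerator

SEED = 20260925
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfg = make_fixtures("small", seed=SEED)
    gen = CohortGenerator(cfg)
    cohort = gen.generate_cohort()
    cohort.write(OUT)
    gen.generate_reference_panels().to_dir(OUT / "panels")
    gen.generate_multistudy_maf().to_tsv(OUT / "multistudy.maf.tsv")
    write_knowledge_base(default_knowledge_base(cfg),
                         OUT / "knowledge_base.tsv")
    cfg.dump(OUT / "generator_config.yaml")

    labels = Counter(cohort.truth.variant_labels.values())
    print(f"simulated {cfg.n_samples} samples, {len(cfg.genes)} genes "
          f"(seed {SEED})")
    print(f"emitted {len(cohort.variants)} variants: "
          f"{labels['somatic']} somatic, {labels['germline']} germline, "
          f"{labels['artifact']} artifact")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
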