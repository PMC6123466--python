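#!/usr/bin/env python
"""Gene recurrence and hotspot discovery against the multi-study reference.

Counts non-silent carriers per gene, then aggregates mutations by amino-acid
position (splice events by junction) and tests positions with >= 3 mutations
in either cohort by two-sided Fisher's exact test, BH-corrected.

Reads results/cohort/ and results/filtered/; writes results/hotspots/.
"""

from pathlib import Path

from tumoronly.filters import get_policy
from tumoronly.hotspots import (MultiStudyMAF, find_hotspots,
                                gene_recurrence_table,
                                hotspot_results_frame)
from tumoronly.io import read_clinical, read_maf

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "hotspots"


def main() -> None:
    variants = read_maf(ROOT / "filtered" / "filtered.maf")
    clinical = read_clinical(ROOT / "cohort" / "clinical.tsv")
    multistudy = MultiStudyMAF.from_tsv(ROOT / "cohort" / "multistudy.maf.tsv")
    n_study = len({v.sample_id for v in variants} |
                  {c.sample_id for c in clinical})

    policy = get_policy("non_silent")
    ns = [v for v in variants if policy.includes(v)]
    OUT.mkdir(parents=True, exist_ok=True)

    recurrence = gene_recurrence_table(ns, policy, n_study)
    recurrence.to_csv(OUT / "gene_recurrence.tsv", sep="\t", index=False,
                      lineterminator="\n", float_format="%.4f")
    top = recurrence.head(5)
    print(f"non-silent recurrence over {n_study} samples; top genes:")
    for row in top.itertuples(index=False):
        print(f"  {row.gene:10s} {row.carriers:4d} carriers "
              f"({row.percent:.1f}%)")

    hotspots = find_hotspots(ns, multistudy, n_study=n_study)
    df = hotspot_results_frame(hotspots)
    df.to_csv(OUT / "hotspots.tsv", sep="\t", index=False,
              lineterminator="\n", float_format="%.6g")
    novel = df[df["novel"]]
    print(f"tested {len(df)} positions against N_ref={multistudy.n_ref}; "
          f"{len(novel)} enriched above reference (q < 0.05):")
    for row in novel.itertuples(index=False):
        print(f"  {row.gene} position {row.protein_position}: "
              f"{row.k_study}/{row.n_study} vs {row.k_ref}/{row.n_ref} "
              f"(q = {row.q:.2g})")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
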