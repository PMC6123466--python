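"""Gene-panel selection and mutation hotspot discovery.

A multi-study reference mutation catalog provides the expected recurrence of
each amino-acid position. Study variants are aggregated by (gene, protein
position); positions with at least three mutations in either cohort are
tested by two-sided Fisher's exact test against the reference, with
Benjamini-Hochberg correction across tested positions. A position is flagged
novel when its adjusted q falls below the configured level and the study
proportion exceeds the reference proportion.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DegenerateInputError, ValidationError
from .filters import ClassPolicy
from .io import VariantRecord


@dataclass
class ReferenceMutation:
    """One mutation in the multi-study reference catalog."""

    gene: str
    protein_position: int
    consequence_class: str
    sample_id: str
    study_id: str


@dataclass
class MultiStudyMAF:
    """Reference mutation catalog with per-study sample totals."""

    records: list[ReferenceMutation]
    study_sample_counts: dict[str, int]

    @property
    def n_ref(self) -> int:
        return sum(self.study_sample_counts.values())

    def validate(self) -> None:
        distinct = len({r.sample_id for r in self.records})
        if self.n_ref < distinct:
            raise ValidationError(
                f"total reference samples {self.n_ref} < distinct sample ids "
                f"{distinct}")
        for r in self.records:
            if r.protein_position < 1:
                raise ValidationError(
                    f"{r.gene}: protein position must be positive")

    def gene_carrier_counts(self) -> dict[str, int]:
        """Distinct reference samples with >= 1 mutation per gene."""
        carriers: dict[str, set[str]] = {}
        for r in self.records:
            carriers.setdefault(r.gene, set()).add(r.sample_id)
        return {g: len(s) for g, s in carriers.items()}

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"gene": r.gene, "protein_position": r.protein_position,
                 "consequence_class": r.consequence_class,
                 "sample_id": r.sample_id, "study_id": r.study_id}
                for r in self.records]
        header = "#" + "\t".join(f"{s}={n}" for s, n
                                 in sorted(self.study_sample_counts.items()))
        body = pd.DataFrame(rows, columns=["gene", "protein_position",
                                           "consequence_class", "sample_id",
                                           "study_id"]).to_csv(
            sep="\t", index=False, lineterminator="\n")
        Path(path).write_text(header + "\n" + body)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MultiStudyMAF":
        text = Path(path).read_text().splitlines()
        if not text or not text[0].startswith("#"):
            raise ValidationError(f"{path}: missing study-size header line")
        counts = {}
        for item in text[0][1:].split("\t"):
            study, n = item.split("=")
            counts[study] = int(n)
        df = pd.read_csv(path, sep="\t", comment="#")
        records = [ReferenceMutation(
            gene=str(r.gene), protein_position=int(r.protein_position),
            consequence_class=str(r.consequence_class),
            sample_id=str(r.sample_id), study_id=str(r.study_id))
            for r in df.itertuples(index=False)]
        obj = cls(records=records, study_sample_counts=counts)
        obj.validate()
        return obj


@dataclass
class DruggabilityTable:
    """Per-gene druggable-category and anti-cancer-drug interaction counts."""

    entries: dict[str, tuple[int, int]] = field(default_factory=dict)

    def categories(self, gene: str) -> int:
        return self.entries.get(gene, (0, 0))[0]

    def interactions(self, gene: str) -> int:
        return self.entries.get(gene, (0, 0))[1]


@dataclass
class HotspotResult:
    """Per-position enrichment test against the reference catalog."""

    gene: str
    protein_position: int | str
    k_study: int
    n_study: int
    k_ref: int
    n_ref: int
    odds_ratio: float
    p: float
    q: float = float("nan")
    novel: bool = False


def parse_protein_position(protein_change: str) -> int | None:
    """First integer in a protein-change string (H1047R -> 1047)."""
    m = re.search(r"\d+", protein_change or "")
    return int(m.group()) if m else None


def hotspot_key(variant: VariantRecord) -> tuple[str, int | str] | None:
    """Aggregation key for hotspot counting.

    Residue-level events key by (gene, protein position); proximal splice
    site events key by (gene, splice-junction id) so recurrent splice
    disruption aggregates as one hotspot even when the underlying genomic
    changes differ.
    """
    pos = parse_protein_position(variant.protein_change or "")
    if pos is None:
        return None
    if variant.consequence_class == "splice_site":
        return (variant.gene, f"splice:{pos}")
    return (variant.gene, pos)


def select_panel_genes(multistudy: MultiStudyMAF,
                       drugs: DruggabilityTable) -> list[dict]:
    """Select genes recurrently mutated in >= 2% of reference cases, or in
    >= 1% when druggable (more than two categories or more than two
    anti-cancer drug interactions)."""
    n_ref = multistudy.n_ref
    if n_ref <= 0:
        raise ConfigError("reference cohort is empty")
    carrier_counts = multistudy.gene_carrier_counts()
    for gene in sorted(set(drugs.entries) - set(carrier_counts)):
        warnings.warn(f"druggability entry for {gene} has no reference "
                      "mutations; ignored")
    selected = []
    for gene in sorted(carrier_counts):
        recurrence = carrier_counts[gene] / n_ref
        druggable = (drugs.categories(gene) > 2
                     or drugs.interactions(gene) > 2)
        if recurrence >= 0.02:
            reason = f"recurrence {recurrence:.3f} >= 0.02"
        elif recurrence >= 0.01 and druggable:
            reason = (f"recurrence {recurrence:.3f} >= 0.01 and druggable "
                      f"({drugs.categories(gene)} categories, "
                      f"{drugs.interactions(gene)} drug interactions)")
        else:
            continue
        selected.append({"gene": gene, "recurrence": recurrence,
                         "reason": reason})
    return selected


def find_hotspots(study_variants: list[VariantRecord],
                  multistudy: MultiStudyMAF,
                  n_study: int,
                  min_count: int = 3,
                  novel_q: float = 0.05) -> list[HotspotResult]:
    """Test recurrently mutated positions for enrichment over the reference.

    Positions need at least ``min_count`` mutations in either cohort to be
    tested. The 2x2 table compares mutation counts against cohort sizes;
    two-sided Fisher p-values are BH-adjusted across tested positions.
    """
    if n_study <= 0:
        raise ConfigError("study cohort size must be positive")
    n_ref = multistudy.n_ref

    study_counts: dict[tuple[str, int | str], int] = {}
    for v in study_variants:
        key = hotspot_key(v)
        if key is None:
            continue    # unparseable protein change: logged upstream, skipped
        study_counts[key] = study_counts.get(key, 0) + 1

    ref_counts: dict[tuple[str, int | str], int] = {}
    for r in multistudy.records:
        if r.consequence_class == "splice_site":
            key = (r.gene, f"splice:{r.protein_position}")
        else:
            key = (r.gene, r.protein_position)
        ref_counts[key] = ref_counts.get(key, 0) + 1

    results = []
    for key in sorted(set(study_counts) | set(ref_counts),
                      key=lambda k: (k[0], str(k[1]))):
        k_study = study_counts.get(key, 0)
        k_ref = ref_counts.get(key, 0)
        if max(k_study, k_ref) < min_count:
            continue
        table = [[k_study, n_study - k_study], [k_ref, n_ref - k_ref]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        results.append(HotspotResult(
            gene=key[0], protein_position=key[1], k_study=k_study,
            n_study=n_study, k_ref=k_ref, n_ref=n_ref,
            odds_ratio=float(odds), p=float(p)))
    if results:
        q = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q = float(qv)
            r.novel = bool(qv < novel_q
                           and r.k_study / r.n_study > r.k_ref / r.n_ref)
    return results


def gene_recurrence_table(variants: list[VariantRecord],
                          policy: ClassPolicy,
                          n_samples: int) -> pd.DataFrame:
    """Per-gene carrier counts and percentages under a class policy.

    A carrier is a sample with at least one qualifying variant; multiple
    hits in the same gene count once.
    """
    if n_samples <= 0:
        raise DegenerateInputError("n_samples must be positive")
    carriers: dict[str, set[str]] = {}
    for v in variants:
        if policy.includes(v):
            carriers.setdefault(v.gene, set()).add(v.sample_id)
    rows = [{"gene": g, "carriers": len(s), "n_samples": n_samples,
             "percent": 100.0 * len(s) / n_samples}
            for g, s in carriers.items()]
    df = pd.DataFrame(rows, columns=["gene", "carriers", "n_samples",
                                     "percent"])
    return df.sort_values(["carriers", "gene"],
                          ascending=[False, True]).reset_index(drop=True)


def hotspot_results_frame(results: list[HotspotResult]) -> pd.DataFrame:
    rows = [{"gene": r.gene, "protein_position": r.protein_position,
             "k_study": r.k_study, "n_study": r.n_study, "k_ref": r.k_ref,
             "n_ref": r.n_ref, "odds_ratio": r.odds_ratio, "p": r.p,
             "q": r.q, "novel": r.novel} for r in results]
    return pd.DataFrame(rows, columns=["gene", "protein_position", "k_study",
                                       "n_study", "k_ref", "n_ref",
                                       "odds_ratio", "p", "q", "novel"])
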