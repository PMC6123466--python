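"""Tumor-only somatic filtering cascade.

Archival tumor cohorts often lack matched normal DNA, so germline variants
and recurrent pipeline artifacts must be removed with population resources
and unmatched-normal panels instead of a paired subtraction. The cascade
applies, in fixed order:

1. restriction to targeted regions;
2. population minor-allele-frequency filter (three resources; strictly
   greater than 0.1% in any removes);
3. unmatched-normal call-count filter (called in >= 10 of the panel removes);
4. exome read-count panel (evidence in >= 1% of panel samples removes);
5. genome read-count panel (evidence in >= 2 samples removes);
6. a binomial log-likelihood-ratio classifier against a sequencing-error
   null (keep iff LLR >= 10 for SNVs/DNPs, >= 6 for indels).

A knowledge-base rescue pass then re-admits calls at known actionable sites
supported by at least 5 reads, 1% VAF and 20x coverage, regardless of the
cascade verdict. Every stage is evaluated for every variant so the trace is
complete; the final status cites the first failing stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .config import FilterThresholds
from .errors import ConfigError, PipelineError, ValidationError
from .io import TargetRegion, VariantRecord

SiteKey = tuple[str, int, str, str]

POPULATION_RESOURCES = ("maf_1000g", "maf_nhlbi", "maf_exac")

STAGES = ("target_restriction", "population_maf", "unmatched_normals",
          "exome_panel", "genome_panel", "llr_classifier")


@dataclass
class ReferencePanels:
    """Population frequencies and unmatched-normal panels used by the cascade.

    ``population_maf`` maps a site key to per-resource minor allele
    frequencies (absence means frequency 0); ``normal_call_counts`` holds the
    number of unmatched normals in which the variant was called; the two
    read-count panels hold per-panel-sample (var_reads, depth) observations —
    sites absent from a panel have no evidence by construction.
    """

    population_maf: dict[SiteKey, tuple[float, float, float]]
    normal_call_counts: dict[SiteKey, int]
    exome_readcount_panel: dict[SiteKey, list[tuple[int, int]]]
    genome_readcount_panel: dict[SiteKey, list[tuple[int, int]]]
    n_unmatched_normals: int = 151
    n_exome_panel: int = 912
    n_genome_panel: int = 87

    def validate(self) -> None:
        for key, count in self.normal_call_counts.items():
            if count > self.n_unmatched_normals:
                raise ValidationError(
                    f"{key}: normal call count {count} exceeds panel size "
                    f"{self.n_unmatched_normals}")
        for key, mafs in self.population_maf.items():
            for maf in mafs:
                if not 0.0 <= maf <= 1.0:
                    raise ValidationError(f"{key}: MAF {maf} outside [0, 1]")

    # -- TSV persistence ----------------------------------------------------

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pop = pd.DataFrame(
            [k + v for k, v in sorted(self.population_maf.items())],
            columns=["chrom", "pos", "ref", "alt", *POPULATION_RESOURCES])
        pop.to_csv(directory / "population_maf.tsv", sep="\t", index=False,
                   lineterminator="\n")
        norm = pd.DataFrame(
            [k + (v,) for k, v in sorted(self.normal_call_counts.items())],
            columns=["chrom", "pos", "ref", "alt", "call_count"])
        norm.to_csv(directory / "normal_calls.tsv", sep="\t", index=False,
                    lineterminator="\n")
        for name, panel in (("exome_readcounts", self.exome_readcount_panel),
                            ("genome_readcounts", self.genome_readcount_panel)):
            rows = [k + (i, vr, dp)
                    for k, obs in sorted(panel.items())
                    for i, (vr, dp) in enumerate(obs)]
            df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                             "panel_sample", "var_reads",
                                             "depth"])
            df.to_csv(directory / f"{name}.tsv", sep="\t", index=False,
                      lineterminator="\n")
        meta = {"n_unmatched_normals": self.n_unmatched_normals,
                "n_exome_panel": self.n_exome_panel,
                "n_genome_panel": self.n_genome_panel}
        (directory / "meta.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def from_dir(cls, directory: str | Path) -> "ReferencePanels":
        directory = Path(directory)
        if not directory.is_dir():
            raise PipelineError("panels", f"panels directory not found: {directory}")
        meta = yaml.safe_load((directory / "meta.yaml").read_text())
        pop_df = pd.read_csv(directory / "population_maf.tsv", sep="\t",
                             dtype={"chrom": str})
        pop = {(r.chrom, int(r.pos), r.ref, r.alt):
               tuple(float(getattr(r, c)) for c in POPULATION_RESOURCES)
               for r in pop_df.itertuples(index=False)}
        norm_df = pd.read_csv(directory / "normal_calls.tsv", sep="\t",
                              dtype={"chrom": str})
        norm = {(r.chrom, int(r.pos), r.ref, r.alt): int(r.call_count)
                for r in norm_df.itertuples(index=False)}
        panels = {}
        for name in ("exome_readcounts", "genome_readcounts"):
            df = pd.read_csv(directory / f"{name}.tsv", sep="\t",
                             dtype={"chrom": str})
            panel: dict[SiteKey, list[tuple[int, int]]] = {}
            for r in df.itertuples(index=False):
                panel.setdefault((r.chrom, int(r.pos), r.ref, r.alt),
                                 []).append((int(r.var_reads), int(r.depth)))
            panels[name] = panel
        obj = cls(population_maf=pop, normal_call_counts=norm,
                  exome_readcount_panel=panels["exome_readcounts"],
                  genome_readcount_panel=panels["genome_readcounts"],
                  n_unmatched_normals=int(meta["n_unmatched_normals"]),
                  n_exome_panel=int(meta["n_exome_panel"]),
                  n_genome_panel=int(meta["n_genome_panel"]))
        obj.validate()
        return obj


@dataclass
class KnowledgeBaseSite:
    """A curated clinically or functionally relevant mutation site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    protein_change: str
    source: str = "curated"
    consequence_class: str = "missense"

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_knowledge_base(path: str | Path) -> list[KnowledgeBaseSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sites = []
    for r in df.itertuples(index=False):
        kwargs = r._asdict()
        kwargs["pos"] = int(kwargs["pos"])
        sites.append(KnowledgeBaseSite(**kwargs))
    return sites


def write_knowledge_base(sites: list[KnowledgeBaseSite],
                         path: str | Path) -> None:
    rows = [{"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
             "gene": s.gene, "protein_change": s.protein_change,
             "source": s.source, "consequence_class": s.consequence_class}
            for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Individual stages
# ---------------------------------------------------------------------------

def merge_regions(regions: list[TargetRegion]) -> list[TargetRegion]:
    """Merge overlapping/adjacent regions per chromosome."""
    merged: list[TargetRegion] = []
    by_chrom: dict[str, list[TargetRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        current = None
        for r in sorted(by_chrom[chrom], key=lambda r: (r.start, r.end)):
            if current is None:
                current = TargetRegion(chrom, r.start, r.end, r.gene)
            elif r.start <= current.end + 1:
                current.end = max(current.end, r.end)
            else:
                merged.append(current)
                current = TargetRegion(chrom, r.start, r.end, r.gene)
        if current is not None:
            merged.append(current)
    return merged


def restrict_to_targets(variants: list[VariantRecord],
                        regions: list[TargetRegion]) -> list[VariantRecord]:
    """Keep variants whose position lies in a target region (inclusive)."""
    if not regions:
        raise ConfigError("empty target region set")
    merged = merge_regions(regions)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in merged:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    kept = []
    for v in variants:
        intervals = by_chrom.get(v.chrom, ())
        if any(start <= v.pos <= end for start, end in intervals):
            kept.append(v)
    return kept


def _population_metric(v: VariantRecord, panels: ReferencePanels) -> float:
    mafs = panels.population_maf.get(v.key)
    return max(mafs) if mafs else 0.0


def filter_population_frequency(
        variants: list[VariantRecord], panels: ReferencePanels,
        thresholds: FilterThresholds,
) -> tuple[list[VariantRecord], list[tuple[bool, float]]]:
    """Remove variants with population MAF strictly above the cutoff in
    any resource; absence from the table means frequency 0."""
    trace, kept = [], []
    for v in variants:
        maf = _population_metric(v, panels)
        ok = maf <= thresholds.pop_maf_max
        trace.append((ok, maf))
        if ok:
            kept.append(v)
    return kept, trace


def filter_unmatched_normal_calls(
        variants: list[VariantRecord], panels: ReferencePanels,
        thresholds: FilterThresholds,
) -> tuple[list[VariantRecord], list[tuple[bool, float]]]:
    """Remove variants called in >= ``normal_call_min`` unmatched normals."""
    trace, kept = [], []
    for v in variants:
        count = panels.normal_call_counts.get(v.key, 0)
        ok = count < thresholds.normal_call_min
        trace.append((ok, float(count)))
        if ok:
            kept.append(v)
    return kept, trace


def _panel_evidence_count(key: SiteKey,
                          panel: dict[SiteKey, list[tuple[int, int]]],
                          thresholds: FilterThresholds) -> int:
    """Count panel samples with qualifying evidence at the site."""
    count = 0
    for var_reads, depth in panel.get(key, ()):
        if depth <= 0:
            continue
        depth_ok = (depth >= thresholds.panel_min_depth
                    if thresholds.panel_depth_inclusive
                    else depth > thresholds.panel_min_depth)
        if (var_reads >= thresholds.panel_min_var_reads
                and var_reads / depth >= thresholds.panel_min_vaf
                and depth_ok):
            count += 1
    return count


def filter_readcount_panel(
        variants: list[VariantRecord], panels: ReferencePanels,
        mode: str, thresholds: FilterThresholds,
) -> tuple[list[VariantRecord], list[tuple[bool, float]]]:
    """Remove variants with recurrent read-count evidence in a normal panel.

    ``exome`` mode removes when the fraction of panel samples with evidence
    reaches ``exome_panel_frac`` of the panel actually loaded; ``genome``
    mode removes at an absolute evidence count of ``genome_panel_count``.
    """
    if mode == "exome":
        panel, size = panels.exome_readcount_panel, panels.n_exome_panel
    elif mode == "genome":
        panel, size = panels.genome_readcount_panel, panels.n_genome_panel
    else:
        raise ConfigError(f"unknown read-count panel mode {mode!r}")
    trace, kept = [], []
    for v in variants:
        count = _panel_evidence_count(v.key, panel, thresholds)
        if mode == "exome":
            metric = count / size
            ok = metric < thresholds.exome_panel_frac
        else:
            metric = float(count)
            ok = count < thresholds.genome_panel_count
        trace.append((ok, metric))
        if ok:
            kept.append(v)
    return kept, trace


def binomial_llr(var_reads: int, depth: int, p_err: float) -> float:
    """Log-likelihood ratio of the observed VAF against an error-rate null.

    ln Binom(x; n, x/n) - ln Binom(x; n, p_err), which reduces to
    n * KL(x/n || p_err) in natural-log units. Large values indicate read
    support far beyond what sequencing error alone explains.
    """
    if depth <= 0:
        raise ValidationError("depth must be positive for LLR classification")
    if not 0 <= var_reads <= depth:
        raise ValidationError("require 0 <= var_reads <= depth")
    p_hat = var_reads / depth
    llr = 0.0
    if var_reads > 0:
        llr += var_reads * math.log(p_hat / p_err)
    if var_reads < depth:
        llr += (depth - var_reads) * math.log((1 - p_hat) / (1 - p_err))
    return llr


def classify_somatic_llr(variant: VariantRecord,
                         thresholds: FilterThresholds) -> tuple[float, bool]:
    """Binomial LLR somatic classifier; keep iff LLR meets the per-type
    threshold (removal below threshold, so an exact tie is kept)."""
    llr = binomial_llr(variant.var_reads, variant.depth, thresholds.p_err)
    cutoff = (thresholds.llr_indel if variant.is_indel
              else thresholds.llr_snv)
    return llr, llr >= cutoff


def rescue_known_hotspots(
        site_readcounts: dict[tuple[str, SiteKey], tuple[int, int]],
        knowledge_base: list[KnowledgeBaseSite],
        thresholds: FilterThresholds,
) -> list[VariantRecord]:
    """Emit calls at knowledge-base sites with qualifying read support.

    ``site_readcounts`` maps (sample_id, site key) to (var_reads, depth).
    Sites in the knowledge base with no read-count data are skipped.
    """
    kb_by_key = {s.key: s for s in knowledge_base}
    rescued = []
    for (sample_id, key), (var_reads, depth) in sorted(site_readcounts.items()):
        site = kb_by_key.get(key)
        if site is None or depth <= 0:
            continue
        if (var_reads >= thresholds.rescue_min_var_reads
                and var_reads / depth >= thresholds.rescue_min_vaf
                and depth >= thresholds.rescue_min_depth):
            ref, alt = key[2], key[3]
            if len(ref) == len(alt):
                vtype = "SNV" if len(ref) == 1 else "DNP"
            else:
                vtype = "INS" if len(alt) > len(ref) else "DEL"
            rescued.append(VariantRecord(
                sample_id=sample_id, gene=site.gene, chrom=key[0],
                pos=key[1], ref=ref, alt=alt, variant_type=vtype,
                consequence_class=site.consequence_class,
                var_reads=var_reads, depth=depth,
                protein_change=site.protein_change))
    return rescued


# ---------------------------------------------------------------------------
# Variant-class policies
# ---------------------------------------------------------------------------

_POLICY_CLASSES = {
    "non_silent": frozenset({"missense", "nonsense", "frameshift",
                             "inframe_indel", "splice_site"}),
    "missense": frozenset({"missense"}),
    "fs_ns": frozenset({"frameshift", "nonsense"}),
    "fs_ns_splice": frozenset({"frameshift", "nonsense", "splice_site"}),
}


@dataclass(frozen=True)
class ClassPolicy:
    """A named consequence-class inclusion rule for carrier definitions.

    The non-silent policy excludes splice-region (only the proximal splice
    site counts), UTR, intronic and silent variants, and RNA-gene variants
    unless the gene is whitelisted (MALAT1 by default).
    """

    name: str
    classes: frozenset[str]
    rna_whitelist: frozenset[str] = frozenset({"MALAT1"})

    def includes(self, variant: VariantRecord) -> bool:
        if variant.consequence_class in self.classes:
            return True
        return (self.name == "non_silent"
                and variant.consequence_class == "rna"
                and variant.gene in self.rna_whitelist)


def get_policy(name: str,
               rna_whitelist: tuple[str, ...] = ("MALAT1",)) -> ClassPolicy:
    if name not in _POLICY_CLASSES:
        raise ConfigError(f"unknown class policy {name!r}; expected one of "
                          + ", ".join(sorted(_POLICY_CLASSES)))
    return ClassPolicy(name=name, classes=_POLICY_CLASSES[name],
                       rna_whitelist=frozenset(rna_whitelist))


def assign_class_sets(variants: list[VariantRecord],
                      policy: ClassPolicy) -> list[VariantRecord]:
    """Subset variants to those qualifying under the policy."""
    return [v for v in variants if policy.includes(v)]


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterTrace:
    """Full per-variant audit of the cascade."""

    entries: pd.DataFrame                 # one row per variant x stage
    final_status: list[str] = field(default_factory=list)


def run_filter_cascade(
        variants: list[VariantRecord],
        panels: ReferencePanels,
        knowledge_base: list[KnowledgeBaseSite],
        thresholds: FilterThresholds,
        regions: list[TargetRegion] | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame, dict]:
    """Apply the full cascade and knowledge-base rescue.

    Returns (retained variants, trace table, summary counts). Every stage is
    evaluated for every on-target variant; the final status names the first
    failing stage; rescue overrides removal at knowledge-base sites.
    """
    if regions is not None:
        on_target = set(id(v) for v in restrict_to_targets(variants, regions))
        target_flags = [id(v) in on_target for v in variants]
    else:
        target_flags = [True] * len(variants)
    working = [v for v, ok in zip(variants, target_flags) if ok]

    stage_traces: dict[str, list[tuple[bool, float]]] = {}
    _, stage_traces["population_maf"] = filter_population_frequency(
        working, panels, thresholds)
    _, stage_traces["unmatched_normals"] = filter_unmatched_normal_calls(
        working, panels, thresholds)
    _, stage_traces["exome_panel"] = filter_readcount_panel(
        working, panels, "exome", thresholds)
    _, stage_traces["genome_panel"] = filter_readcount_panel(
        working, panels, "genome", thresholds)
    llr_trace = []
    for v in working:
        llr, keep = classify_somatic_llr(v, thresholds)
        llr_trace.append((keep, llr))
    stage_traces["llr_classifier"] = llr_trace

    kb_keys = {s.key for s in knowledge_base}
    site_readcounts = {(v.sample_id, v.key): (v.var_reads, v.depth)
                       for v in working if v.key in kb_keys}
    rescued_records = rescue_known_hotspots(site_readcounts, knowledge_base,
                                            thresholds)
    rescued_ids = {(r.sample_id, r.key) for r in rescued_records}

    rows = []
    retained: list[VariantRecord] = []
    statuses = []
    post_stages = [s for s in STAGES if s != "target_restriction"]
    for i, v in enumerate(working):
        first_fail = None
        for stage in post_stages:
            ok, metric = stage_traces[stage][i]
            rows.append({"sample_id": v.sample_id, "chrom": v.chrom,
                         "pos": v.pos, "ref": v.ref, "alt": v.alt,
                         "stage": stage, "passed": ok, "metric": metric})
            if not ok and first_fail is None:
                first_fail = stage
        if (v.sample_id, v.key) in rescued_ids:
            status = "rescued" if first_fail is not None else "retained"
            retained.append(v)
        elif first_fail is None:
            status = "retained"
            retained.append(v)
        else:
            status = f"removed:{first_fail}"
        statuses.append(status)

    trace_df = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "stage",
                       "passed", "metric"])
    status_counts = pd.Series(statuses).value_counts().to_dict() if statuses else {}
    summary = {
        "input": len(variants),
        "on_target": len(working),
        "off_target_removed": len(variants) - len(working),
        "retained": len(retained),
        "rescued": sum(1 for s in statuses if s == "rescued"),
        "status_counts": status_counts,
        "stage_removal_counts": {
            stage: sum(1 for s in statuses if s == f"removed:{stage}")
            for stage in post_stages},
    }
    return retained, trace_df, summary


# ---------------------------------------------------------------------------
# Sample-level QC and mutation burden
# ---------------------------------------------------------------------------

def sample_coverage_qc(coverage_fraction: dict[str, float],
                       thresholds: FilterThresholds) -> dict[str, bool]:
    """Pass iff the fraction of targeted bases at adequate depth reaches the
    QC minimum (at least 80% covered at greater than 20x by default)."""
    if not coverage_fraction:
        raise PipelineError("qc", "missing per-sample coverage summary")
    result = {}
    for sample, frac in coverage_fraction.items():
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(
                f"{sample}: coverage fraction {frac} outside [0, 1]")
        result[sample] = frac >= thresholds.qc_min_fraction
    if not any(result.values()):
        raise PipelineError("qc", "no analyzable samples: all failed coverage QC")
    return result


def mutations_per_mb(m: int, tiled_length_bp: int, correction: float = 1.0) -> float:
    """Mutation burden in mutations per megabase of assayed sequence.

    ``correction`` (>= 1) accounts for genes not assayed by the panel.
    """
    if tiled_length_bp <= 0:
        raise ValidationError("tiled length must be positive")
    if correction < 1.0:
        raise ValidationError("correction factor must be >= 1")
    if m < 0:
        raise ValidationError("mutation count must be >= 0")
    return correction * m / (tiled_length_bp / 1e6)


def burden_summary(per_sample_counts: dict[str, int], tiled_length_bp: int,
                   correction: float = 1.0) -> dict:
    """Cohort mutations-per-MB summary; zero-mutation samples are flagged
    and excluded from the range statistics."""
    rates = {s: mutations_per_mb(m, tiled_length_bp, correction)
             for s, m in per_sample_counts.items()}
    nonzero = [r for s, r in rates.items() if per_sample_counts[s] > 0]
    excluded = sorted(s for s, m in per_sample_counts.items() if m == 0)
    summary = {"per_sample": rates, "excluded_zero_mutation": excluded}
    if nonzero:
        summary.update(mean=sum(nonzero) / len(nonzero),
                       min=min(nonzero), max=max(nonzero))
    return summary
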