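"""Synthetic targeted-capture tumor-only cohort generator.

Emulates the statistical structure the downstream analysis assumes, so every
stage is testable without restricted patient data:

* somatic clonal heterozygous variants with expected VAF = purity / 2, read
  counts binomially sampled at negative-binomial depths with a per-read
  miscall rate;
* germline contaminants tied to population allele frequencies (carrier
  probability proportional to heterozygote frequency), VAF jittered around
  0.5 with a symmetric Beta;
* recurrent low-VAF artifacts shared with the unmatched-normal panels;
* PAM50-like subtype labels with per-gene enrichment weights, standard
  clinical covariates, and exponential/Weibull survival times whose hazards
  multiply by exp(log-HR) for mutation carriers.

Every emitted variant carries exactly one truth label in
{somatic, germline, artifact}. One root seed; each stage derives its own
child stream from a fixed label, so adding a stage never perturbs others.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, PipelineError
from .filters import ReferencePanels, SiteKey
from .hotspots import MultiStudyMAF, ReferenceMutation
from .io import (ClinicalRecord, SurvivalRecord, TargetRegion, VariantRecord,
                 write_bed, write_clinical, write_maf, write_survival)

_BASES = np.array(["A", "C", "G", "T"])
_AA = "ARNDCQEGHILKMFPSTWYV"


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Derive a deterministic child stream from the root seed and a label."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())]))


@dataclass
class GeneSpec:
    """Generative description of one panel gene."""

    name: str
    somatic_rate: float = 0.05
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "missense": 0.62, "nonsense": 0.08, "frameshift": 0.10,
        "inframe_indel": 0.03, "splice_site": 0.05, "splice_region": 0.03,
        "silent": 0.09})
    log_hr: dict[str, float] = field(default_factory=dict)   # per endpoint
    subtype_weights: dict[str, float] = field(default_factory=dict)
    reference_freq: float = 0.05        # recurrence in the multi-study MAF
    hotspot_position: int | None = None
    hotspot_weight: float = 0.0         # fraction of mutations at the hotspot
    protein_length: int = 500
    chrom: str = ""
    start: int = 0

    @property
    def coding_length(self) -> int:
        return 3 * self.protein_length


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    n_samples: int = 400
    genes: list[GeneSpec] = field(default_factory=lambda: default_genes())
    purity_mean: float = 0.65
    purity_sd: float = 0.15
    depth_mean: float = 140.0
    depth_dispersion: float = 3.0
    error_rate: float = 0.005
    germline_rate: float = 2.0          # expected contaminants per sample
    n_germline_pool: int = 40
    germline_maf_range: tuple[float, float] = (3e-4, 0.05)
    germline_vaf_concentration: float = 60.0   # Beta(a=a) around 0.5
    artifact_rate: float = 5.0          # expected recurrent sites per cohort
    artifact_sample_prevalence: float = 0.20
    artifact_panel_prevalence: float = 0.05
    artifact_normal_call_rate: float = 0.15
    n_unmatched_normals: int = 151
    n_exome_panel: int = 912
    n_genome_panel: int = 87
    survival_dist: str = "exponential"
    baseline_scale: float = 20.0        # years; mean time at zero covariates
    weibull_shape: float = 1.0
    admin_censor_time: float = 25.0     # years
    censor_rate: float = 0.02           # per year, random censoring
    subtype_props: dict[str, float] = field(default_factory=lambda: {
        "LumA": 0.45, "LumB": 0.35, "HER2E": 0.10, "Basal": 0.05,
        "Normal": 0.05})
    endpoints: tuple[str, ...] = ("BCSS", "RFS")
    reference_study_sizes: tuple[int, ...] = (500, 300, 200)
    mpmb_correction: float = 1.3
    qc_beta: tuple[float, float] = (30.0, 1.5)  # coverage-fraction model
    seed: int = 0

    def __post_init__(self) -> None:
        genes = []
        for i, g in enumerate(self.genes):
            if isinstance(g, dict):
                g = GeneSpec(**g)
            if not g.chrom:
                g.chrom = str(i % 22 + 1)
            if not g.start:
                g.start = 1_000_000 * (i + 1)
            genes.append(g)
        self.genes = genes

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        if not self.genes:
            raise ConfigError("gene list must be non-empty")
        for p in (self.error_rate, self.artifact_sample_prevalence,
                  self.artifact_panel_prevalence,
                  self.artifact_normal_call_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if not 0.0 < self.purity_mean <= 1.0:
            raise ConfigError("purity mean must be in (0, 1]")
        if self.depth_mean < 0:
            raise ConfigError("depth mean must be nonnegative")
        for size in (self.n_unmatched_normals, self.n_exome_panel,
                     self.n_genome_panel):
            if size <= 0:
                raise ConfigError("panel sizes must be positive")
        for g in self.genes:
            if not 0.0 <= g.somatic_rate <= 1.0:
                raise ConfigError(
                    f"{g.name}: somatic rate {g.somatic_rate} outside [0, 1]")
            if not 0.0 <= g.reference_freq <= 1.0:
                raise ConfigError(
                    f"{g.name}: reference frequency outside [0, 1]")
        total = sum(self.subtype_props.values())
        if not np.isclose(total, 1.0):
            raise ConfigError(f"subtype proportions sum to {total}, not 1")
        if self.survival_dist not in ("exponential", "weibull"):
            raise ConfigError(f"unknown survival distribution "
                              f"{self.survival_dist!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def default_genes() -> list[GeneSpec]:
    """A compact panel echoing the recurrently mutated genes of ER+ breast
    cancer, with literature-typical recurrence rates and effect directions."""
    return [
        GeneSpec("PIK3CA", somatic_rate=0.40, reference_freq=0.30,
                 hotspot_position=1047, hotspot_weight=0.35,
                 protein_length=1068,
                 log_hr={"BCSS": -0.30, "RFS": -0.25},
                 subtype_weights={"LumA": 1.2, "Basal": 0.4}),
        GeneSpec("TP53", somatic_rate=0.15, reference_freq=0.25,
                 hotspot_position=273, hotspot_weight=0.15,
                 protein_length=393,
                 log_hr={"BCSS": 0.50, "RFS": 0.45},
                 subtype_weights={"Basal": 3.0, "HER2E": 2.0, "LumA": 0.5}),
        GeneSpec("MAP3K1", somatic_rate=0.12, reference_freq=0.08,
                 protein_length=1512,
                 class_mix={"missense": 0.30, "nonsense": 0.15,
                            "frameshift": 0.40, "inframe_indel": 0.05,
                            "splice_site": 0.05, "silent": 0.05},
                 log_hr={"BCSS": -0.40, "RFS": -0.35},
                 subtype_weights={"LumA": 1.5, "Basal": 0.3}),
        GeneSpec("CDH1", somatic_rate=0.10, reference_freq=0.10,
                 protein_length=882,
                 class_mix={"missense": 0.25, "nonsense": 0.25,
                            "frameshift": 0.35, "splice_site": 0.05,
                            "silent": 0.10}),
        GeneSpec("GATA3", somatic_rate=0.09, reference_freq=0.10,
                 protein_length=444,
                 class_mix={"missense": 0.20, "nonsense": 0.15,
                            "frameshift": 0.45, "splice_site": 0.15,
                            "silent": 0.05},
                 subtype_weights={"LumB": 2.0}),
        GeneSpec("MALAT1", somatic_rate=0.10, reference_freq=0.05,
                 protein_length=800,
                 class_mix={"rna": 1.0}),
        GeneSpec("NF1", somatic_rate=0.03, reference_freq=0.03,
                 protein_length=2818,
                 class_mix={"missense": 0.35, "nonsense": 0.25,
                            "frameshift": 0.30, "splice_site": 0.05,
                            "silent": 0.05},
                 log_hr={"BCSS": 0.60, "RFS": 0.55},
                 subtype_weights={"HER2E": 4.0}),
        GeneSpec("DDR1", somatic_rate=0.03, reference_freq=0.01,
                 protein_length=913,
                 log_hr={"BCSS": 0.70, "RFS": 0.60}),
        GeneSpec("ESR1", somatic_rate=0.02, reference_freq=0.01,
                 hotspot_position=537, hotspot_weight=0.40,
                 protein_length=595),
        GeneSpec("ATM", somatic_rate=0.04, reference_freq=0.03,
                 protein_length=3056,
                 subtype_weights={"LumB": 1.8}),
    ]


@dataclass
class CohortTruth:
    """Ground-truth labels for a generated cohort."""

    variant_labels: dict[str, str]              # "sample|chrom|pos|ref|alt"
    gene_log_hr: dict[str, dict[str, float]]
    sample_purity: dict[str, float]
    mpmb_correction: float

    @staticmethod
    def label_key(sample_id: str, key: SiteKey) -> str:
        return "|".join([sample_id, key[0], str(key[1]), key[2], key[3]])

    def label_of(self, v: VariantRecord) -> str:
        return self.variant_labels[self.label_key(v.sample_id, v.key)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class CohortData:
    """All tables for one synthetic cohort run."""

    variants: list[VariantRecord]
    clinical: list[ClinicalRecord]
    survival: list[SurvivalRecord]
    truth: CohortTruth
    coverage_fraction: dict[str, float]
    regions: list[TargetRegion]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_maf(self.variants, outdir / "variants.maf")
        write_clinical(self.clinical, outdir / "clinical.tsv")
        write_survival(self.survival, outdir / "survival.tsv")
        write_bed(self.regions, outdir / "targets.bed")
        self.truth.to_json(outdir / "truth.json")
        cov = "\n".join(f"{s}\t{f:.6f}"
                        for s, f in sorted(self.coverage_fraction.items()))
        (outdir / "coverage.tsv").write_text(
            "sample_id\tfrac_bases_gt20x\n" + cov + "\n")


def simulate_readcounts(true_vaf: float,
                        depth_params: tuple[float, float],
                        error_rate: float,
                        rng: np.random.Generator | int) -> tuple[int, int]:
    """Draw (var_reads, depth) for one site.

    Depth is negative-binomial with the given (mean, dispersion); supporting
    reads are binomial at the miscall-adjusted allele fraction
    ``vaf * (1 - e) + (1 - vaf) * e / 3`` (a wrong call lands on the variant
    base a third of the time).
    """
    if not 0.0 <= true_vaf <= 1.0:
        raise ConfigError(f"true VAF {true_vaf} outside [0, 1]")
    mean, dispersion = depth_params
    if mean < 0:
        raise ConfigError(f"depth mean must be nonnegative, got {mean}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = dispersion / (dispersion + mean)
    depth = int(rng.negative_binomial(dispersion, p)) if mean > 0 else 0
    p_read = true_vaf * (1 - error_rate) + (1 - true_vaf) * error_rate / 3
    var_reads = int(rng.binomial(depth, p_read)) if depth > 0 else 0
    return var_reads, depth


def _protein_change(cls: str, pos: int, rng: np.random.Generator) -> str:
    a, b = rng.choice(len(_AA), size=2)
    if cls == "missense":
        return f"{_AA[a]}{pos}{_AA[b]}"
    if cls == "nonsense":
        return f"{_AA[a]}{pos}*"
    if cls == "frameshift":
        return f"{_AA[a]}{pos}fs"
    if cls == "inframe_indel":
        return f"{_AA[a]}{pos}del"
    if cls == "splice_site":
        return f"X{pos}_splice"
    return f"{_AA[a]}{pos}{_AA[a]}"


def _alleles(cls: str, rng: np.random.Generator) -> tuple[str, str, str]:
    """(ref, alt, variant_type) consistent with the consequence class."""
    if cls == "frameshift":
        if rng.random() < 0.5:
            return "A", "AT", "INS"
        return "AT", "A", "DEL"
    if cls == "inframe_indel":
        return "AGCT", "A", "DEL"
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return str(_BASES[i]), str(_BASES[j]), "SNV"


class CohortGenerator:
    """Stateful generator: cohort first, then panels and reference MAF."""

    def __init__(self, config: GeneratorConfig):
        config.validate()
        self.config = config
        self._cohort: CohortData | None = None
        self._germline_pool: list[dict] | None = None
        self._artifact_sites: list[dict] | None = None

    # -- stage 1: cohort ----------------------------------------------------

    def generate_cohort(self) -> CohortData:
        cfg = self.config
        sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]

        rng_p = child_rng(cfg.seed, "purity")
        purity = np.clip(rng_p.normal(cfg.purity_mean, cfg.purity_sd,
                                      cfg.n_samples), 0.05, 1.0)

        rng_sub = child_rng(cfg.seed, "subtype")
        subtype_names = list(cfg.subtype_props)
        probs = np.array([cfg.subtype_props[s] for s in subtype_names])
        subtypes = rng_sub.choice(subtype_names, size=cfg.n_samples,
                                  p=probs / probs.sum())

        variants: list[VariantRecord] = []
        labels: dict[str, str] = {}

        rng_som = child_rng(cfg.seed, "somatic")
        for g in cfg.genes:
            weights = np.array([g.subtype_weights.get(s, 1.0)
                                for s in subtypes])
            p_mut = np.clip(g.somatic_rate * weights, 0.0, 1.0)
            carriers = rng_som.random(cfg.n_samples) < p_mut
            classes = list(g.class_mix)
            class_p = np.array([g.class_mix[c] for c in classes], float)
            class_p = class_p / class_p.sum()
            for i in np.flatnonzero(carriers):
                cls = str(rng_som.choice(classes, p=class_p))
                if (g.hotspot_position is not None
                        and cls in ("missense", "splice_site")
                        and rng_som.random() < g.hotspot_weight):
                    ppos = g.hotspot_position
                else:
                    ppos = int(rng_som.integers(1, g.protein_length + 1))
                ref, alt, vtype = _alleles(cls, rng_som)
                pos = g.start + 3 * (ppos - 1)
                vaf = purity[i] / 2.0
                var_reads, depth = simulate_readcounts(
                    vaf, (cfg.depth_mean, cfg.depth_dispersion),
                    cfg.error_rate, rng_som)
                depth = max(depth, 1)
                rec = VariantRecord(
                    sample_id=sample_ids[i], gene=g.name, chrom=g.chrom,
                    pos=pos, ref=ref, alt=alt, variant_type=vtype,
                    consequence_class=cls, var_reads=min(var_reads, depth),
                    depth=depth,
                    protein_change=_protein_change(cls, ppos, rng_som))
                variants.append(rec)
                labels[CohortTruth.label_key(rec.sample_id, rec.key)] = "somatic"

        self._germline_pool = self._make_germline_pool()
        rng_germ = child_rng(cfg.seed, "germline-carriers")
        het = np.array([2 * s["maf"] * (1 - s["maf"])
                        for s in self._germline_pool])
        if het.sum() > 0:
            carry_p = np.clip(cfg.germline_rate * het / het.sum(), 0.0, 1.0)
        else:
            carry_p = np.zeros_like(het)
        a = cfg.germline_vaf_concentration
        for i, sid in enumerate(sample_ids):
            hits = np.flatnonzero(rng_germ.random(len(carry_p)) < carry_p)
            for j in hits:
                site = self._germline_pool[j]
                vaf = float(rng_germ.beta(a, a))     # jitter around 0.5
                var_reads, depth = simulate_readcounts(
                    vaf, (cfg.depth_mean, cfg.depth_dispersion),
                    cfg.error_rate, rng_germ)
                depth = max(depth, 1)
                rec = VariantRecord(
                    sample_id=sid, gene=site["gene"], chrom=site["chrom"],
                    pos=site["pos"], ref=site["ref"], alt=site["alt"],
                    variant_type=site["vtype"],
                    consequence_class=site["cls"],
                    var_reads=min(var_reads, depth), depth=depth,
                    protein_change=site["protein_change"])
                key = CohortTruth.label_key(sid, rec.key)
                if key not in labels:
                    variants.append(rec)
                    labels[key] = "germline"

        self._artifact_sites = self._make_artifact_sites()
        rng_art = child_rng(cfg.seed, "artifact-occurrences")
        for site in self._artifact_sites:
            present = rng_art.random(cfg.n_samples) < cfg.artifact_sample_prevalence
            for i in np.flatnonzero(present):
                vaf = float(rng_art.uniform(0.01, 0.10))
                var_reads, depth = simulate_readcounts(
                    vaf, (cfg.depth_mean, cfg.depth_dispersion),
                    cfg.error_rate, rng_art)
                depth = max(depth, 1)
                rec = VariantRecord(
                    sample_id=sample_ids[i], gene=site["gene"],
                    chrom=site["chrom"], pos=site["pos"], ref=site["ref"],
                    alt=site["alt"], variant_type=site["vtype"],
                    consequence_class=site["cls"],
                    var_reads=min(var_reads, depth), depth=depth,
                    protein_change=site["protein_change"])
                key = CohortTruth.label_key(rec.sample_id, rec.key)
                if key not in labels:
                    variants.append(rec)
                    labels[key] = "artifact"

        clinical = self._make_clinical(sample_ids, subtypes)
        survival = self._make_survival(sample_ids, variants, labels)
        coverage = self._make_coverage(sample_ids)

        truth = CohortTruth(
            variant_labels=labels,
            gene_log_hr={g.name: dict(g.log_hr) for g in cfg.genes},
            sample_purity={sid: float(p)
                           for sid, p in zip(sample_ids, purity)},
            mpmb_correction=cfg.mpmb_correction)
        regions = self.target_regions()
        self._cohort = CohortData(variants=variants, clinical=clinical,
                                  survival=survival, truth=truth,
                                  coverage_fraction=coverage, regions=regions)
        return self._cohort

    def target_regions(self) -> list[TargetRegion]:
        return [TargetRegion(g.chrom, g.start,
                             g.start + g.coding_length - 1, g.name)
                for g in self.config.genes]

    def _make_germline_pool(self) -> list[dict]:
        cfg = self.config
        rng = child_rng(cfg.seed, "germline-pool")
        lo, hi = cfg.germline_maf_range
        sites = []
        for k in range(cfg.n_germline_pool):
            g = cfg.genes[int(rng.integers(len(cfg.genes)))]
            ppos = int(rng.integers(1, g.protein_length + 1))
            cls = "missense" if rng.random() < 0.7 else "silent"
            ref, alt, vtype = _alleles(cls, rng)
            maf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            sites.append({"gene": g.name, "chrom": g.chrom,
                          "pos": g.start + 3 * (ppos - 1) + 1,
                          "ref": ref, "alt": alt, "vtype": vtype,
                          "cls": cls, "maf": maf,
                          "protein_change": _protein_change(cls, ppos, rng)})
        # one site per genomic key
        seen, unique = set(), []
        for s in sites:
            key = (s["chrom"], s["pos"], s["ref"], s["alt"])
            if key not in seen:
                seen.add(key)
                unique.append(s)
        return unique

    def _make_artifact_sites(self) -> list[dict]:
        cfg = self.config
        rng = child_rng(cfg.seed, "artifact-sites")
        n_sites = int(rng.poisson(cfg.artifact_rate))
        sites = []
        for k in range(n_sites):
            g = cfg.genes[int(rng.integers(len(cfg.genes)))]
            ppos = int(rng.integers(1, g.protein_length + 1))
            cls = "missense"
            ref, alt, vtype = _alleles(cls, rng)
            sites.append({"gene": g.name, "chrom": g.chrom,
                          "pos": g.start + 3 * (ppos - 1) + 2,
                          "ref": ref, "alt": alt, "vtype": vtype, "cls": cls,
                          "protein_change": _protein_change(cls, ppos, rng)})
        seen, unique = set(), []
        for s in sites:
            key = (s["chrom"], s["pos"], s["ref"], s["alt"])
            if key not in seen:
                seen.add(key)
                unique.append(s)
        return unique

    def _make_clinical(self, sample_ids, subtypes) -> list[ClinicalRecord]:
        cfg = self.config
        rng = child_rng(cfg.seed, "clinical")
        records = []
        for sid, subtype in zip(sample_ids, subtypes):
            age = float(np.clip(rng.normal(65.0, 10.0), 30.0, 95.0))
            grade = int(rng.choice([1, 2, 3], p=[0.20, 0.45, 0.35]))
            nodes = int(rng.poisson(1.5))
            size = int(rng.choice([1, 2, 3, 4], p=[0.30, 0.45, 0.20, 0.05]))
            her2_amp = bool(subtype == "HER2E" and rng.random() < 0.8)
            records.append(ClinicalRecord(
                sample_id=sid, age=age, grade=grade, nodes_positive=nodes,
                tumor_size_category=size, er_status=True,
                pr_status=bool(rng.random() < 0.7),
                her2_status=her2_amp, her2_amplified=her2_amp,
                subtype=str(subtype)))
        return records

    def _make_survival(self, sample_ids, variants, labels) -> list[SurvivalRecord]:
        cfg = self.config
        rng = child_rng(cfg.seed, "survival")
        # carrier status from true somatic protein-altering variants
        carrier: dict[str, set[str]] = {sid: set() for sid in sample_ids}
        damaging = {"missense", "nonsense", "frameshift", "inframe_indel",
                    "splice_site"}
        for v in variants:
            key = CohortTruth.label_key(v.sample_id, v.key)
            if labels[key] == "somatic" and v.consequence_class in damaging:
                carrier[v.sample_id].add(v.gene)
        records = []
        for endpoint in cfg.endpoints:
            loghr = {g.name: g.log_hr.get(endpoint, 0.0) for g in cfg.genes}
            for sid in sample_ids:
                eta = sum(loghr[g] for g in sorted(carrier[sid]))
                hazard_scale = cfg.baseline_scale * np.exp(-eta)
                if cfg.survival_dist == "exponential":
                    t_event = float(rng.exponential(hazard_scale))
                else:
                    t_event = float(hazard_scale
                                    * rng.weibull(cfg.weibull_shape))
                t_cens = min(cfg.admin_censor_time,
                             float(rng.exponential(1.0 / cfg.censor_rate))
                             if cfg.censor_rate > 0 else np.inf)
                time = max(min(t_event, t_cens), 1e-3)
                event = int(t_event <= t_cens)
                records.append(SurvivalRecord(sample_id=sid,
                                              endpoint=endpoint,
                                              time=time, event=event))
        return records

    def _make_coverage(self, sample_ids) -> dict[str, float]:
        cfg = self.config
        rng = child_rng(cfg.seed, "coverage")
        a, b = cfg.qc_beta
        return {sid: float(rng.beta(a, b)) for sid in sample_ids}

    # -- stage 2: panels ----------------------------------------------------

    def generate_reference_panels(self) -> ReferencePanels:
        if self._cohort is None:
            raise PipelineError(
                "panels", "generate_cohort must be called before "
                "generate_reference_panels")
        cfg = self.config
        rng = child_rng(cfg.seed, "panels")

        population: dict[SiteKey, tuple[float, float, float]] = {}
        normal_calls: dict[SiteKey, int] = {}
        exome: dict[SiteKey, list[tuple[int, int]]] = {}
        genome: dict[SiteKey, list[tuple[int, int]]] = {}

        for site in self._germline_pool or []:
            key = (site["chrom"], site["pos"], site["ref"], site["alt"])
            maf = site["maf"]
            population[key] = (maf, maf, maf)
            het = 2 * maf * (1 - maf) + maf ** 2
            normal_calls[key] = int(rng.binomial(cfg.n_unmatched_normals, het))
            for panel, size in ((exome, cfg.n_exome_panel),
                                (genome, cfg.n_genome_panel)):
                n_carriers = int(rng.binomial(size, het))
                if n_carriers:
                    panel[key] = [self._evidence_readcounts(rng, vaf=0.5)
                                  for _ in range(n_carriers)]

        for site in self._artifact_sites or []:
            key = (site["chrom"], site["pos"], site["ref"], site["alt"])
            normal_calls[key] = int(rng.binomial(
                cfg.n_unmatched_normals, cfg.artifact_normal_call_rate))
            for panel, size in ((exome, cfg.n_exome_panel),
                                (genome, cfg.n_genome_panel)):
                n_evidence = int(rng.binomial(size,
                                              cfg.artifact_panel_prevalence))
                if n_evidence:
                    panel[key] = [self._evidence_readcounts(
                        rng, vaf=float(rng.uniform(0.02, 0.10)))
                        for _ in range(n_evidence)]

        panels = ReferencePanels(
            population_maf=population, normal_call_counts=normal_calls,
            exome_readcount_panel=exome, genome_readcount_panel=genome,
            n_unmatched_normals=cfg.n_unmatched_normals,
            n_exome_panel=cfg.n_exome_panel,
            n_genome_panel=cfg.n_genome_panel)
        panels.validate()
        return panels

    def _evidence_readcounts(self, rng: np.random.Generator,
                             vaf: float) -> tuple[int, int]:
        """Read counts guaranteed to qualify as panel evidence."""
        cfg = self.config
        p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
        depth = max(20, int(rng.negative_binomial(cfg.depth_dispersion, p)))
        var_reads = int(rng.binomial(depth, vaf))
        floor = max(3, int(np.ceil(0.01 * depth)))
        return max(var_reads, floor), depth

    # -- stage 3: multi-study reference MAF ---------------------------------

    def generate_multistudy_maf(self) -> MultiStudyMAF:
        cfg = self.config
        if not cfg.genes:
            raise ConfigError("gene list must be non-empty")
        rng = child_rng(cfg.seed, "multistudy")
        sizes = np.asarray(cfg.reference_study_sizes, int)
        n_ref = int(sizes.sum())
        study_of = np.repeat(np.arange(len(sizes)), sizes)
        records: list[ReferenceMutation] = []
        for g in cfg.genes:
            n_mut = int(rng.binomial(n_ref, g.reference_freq))
            # distinct carrier samples per gene; samples may recur across
            # genes (multi-mutation reference cases)
            sample_idx = rng.choice(n_ref, size=n_mut, replace=False)
            classes = list(g.class_mix)
            class_p = np.array([g.class_mix[c] for c in classes], float)
            class_p = class_p / class_p.sum()
            for si in sorted(int(i) for i in sample_idx):
                cls = str(rng.choice(classes, p=class_p))
                if (g.hotspot_position is not None
                        and rng.random() < g.hotspot_weight):
                    ppos = g.hotspot_position
                else:
                    ppos = int(rng.integers(1, g.protein_length + 1))
                records.append(ReferenceMutation(
                    gene=g.name, protein_position=ppos,
                    consequence_class=cls,
                    sample_id=f"ref{si:05d}",
                    study_id=f"study{study_of[si]}"))
        study_sizes = {f"study{i}": int(s) for i, s in enumerate(sizes)}
        return MultiStudyMAF(records=records, study_sample_counts=study_sizes)


def generate_cohort(config: GeneratorConfig):
    """One-shot convenience: returns (variants, clinical, survival, truth)."""
    data = CohortGenerator(config).generate_cohort()
    return data.variants, data.clinical, data.survival, data.truth
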