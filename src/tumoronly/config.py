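"""Run configuration: filter thresholds and analysis settings.

Threshold defaults encode the published tumor-only filtering rules exactly as
printed: population minor-allele frequency strictly greater than 0.1% removes;
10 or more calls among the unmatched normals removes; panel evidence requires
at least 3 supporting reads, 1% VAF and 20x coverage; the exome panel removes
at an evidence fraction of at least 1%, the genome panel at a count of at
least 2; the binomial log-likelihood-ratio classifier removes below 10
(SNV/DNP) or below 6 (indels); knowledge-base rescue requires at least 5
supporting reads; sample QC requires at least 80% of targeted bases covered
at greater than 20x.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class FilterThresholds:
    """Thresholds of the tumor-only somatic filtering cascade."""

    pop_maf_max: float = 0.001          # strictly-greater removes
    normal_call_min: int = 10           # >= removes (of n1 unmatched normals)
    panel_min_var_reads: int = 3        # panel-sample evidence rule (all >=)
    panel_min_vaf: float = 0.01
    panel_min_depth: int = 20
    panel_depth_inclusive: bool = True  # ">= 20x" in the filter rule
    exome_panel_frac: float = 0.01      # evidence fraction >= removes
    genome_panel_count: int = 2         # evidence count >= removes
    llr_snv: float = 10.0               # keep iff llr >= threshold
    llr_indel: float = 6.0
    p_err: float = 0.005                # sequencing-error null rate
    rescue_min_var_reads: int = 5       # knowledge-base rescue (all >=)
    rescue_min_vaf: float = 0.01
    rescue_min_depth: int = 20
    qc_min_fraction: float = 0.80       # >= passes
    qc_depth: int = 20                  # "greater than 20x" for QC: strict
    qc_depth_inclusive: bool = False

    def validate(self) -> None:
        for name in ("pop_maf_max", "panel_min_vaf", "exome_panel_frac",
                     "p_err", "rescue_min_vaf", "qc_min_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("normal_call_min", "panel_min_var_reads",
                     "panel_min_depth", "genome_panel_count",
                     "rescue_min_var_reads", "rescue_min_depth", "qc_depth"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be nonnegative, got {v}")


@dataclass
class RunConfig:
    """Resolved end-to-end run configuration."""

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    seed: int = 0
    permutations: int = 1000
    ties: str = "efron"
    split_at: float | None = 5.0
    top_k_cooccurrence: int = 7
    hotspot_q: float = 0.05
    reportable_q: float = 0.2
    ks_alpha: float = 0.05
    gate_non_silent: int = 15
    gate_truncating: int = 8
    add_one_permutation_p: bool = False
    rna_whitelist: tuple[str, ...] = ("MALAT1",)
    endpoints: tuple[str, ...] = ("BCSS", "RFS")
    policies: tuple[str, ...] = ("non_silent", "fs_ns")

    def validate(self) -> None:
        self.thresholds.validate()
        if self.permutations < 1:
            raise ConfigError("permutations must be >= 1")
        if self.ties not in ("efron", "breslow"):
            raise ConfigError(f"unknown ties method {self.ties!r}")
        if not 0 < self.reportable_q <= 1:
            raise ConfigError("reportable_q must be in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    def dump(self, path: str | Path) -> None:
        """Echo the fully resolved configuration for provenance."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


_THRESHOLD_FIELDS = {f.name for f in dataclasses.fields(FilterThresholds)}
_RUN_FIELDS = {f.name for f in dataclasses.fields(RunConfig)} - {"thresholds"}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; unknown keys are a hard error.

    An empty or absent file yields the full default configuration. Threshold
    overrides may be given either under a ``thresholds:`` mapping or as
    top-level keys.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)

    thr_kwargs: dict = {}
    run_kwargs: dict = {}
    nested = raw.pop("thresholds", {})
    if not isinstance(nested, dict):
        raise ConfigError("'thresholds' must be a mapping")
    for key, value in nested.items():
        if key not in _THRESHOLD_FIELDS:
            raise ConfigError(f"unknown threshold key {key!r}")
        thr_kwargs[key] = value
    for key, value in raw.items():
        if key in _THRESHOLD_FIELDS:
            thr_kwargs[key] = value
        elif key in _RUN_FIELDS:
            if isinstance(value, list):
                value = tuple(value)
            run_kwargs[key] = value
        else:
            raise ConfigError(f"unknown configuration key {key!r}")

    cfg = RunConfig(thresholds=FilterThresholds(**thr_kwargs), **run_kwargs)
    cfg.validate()
    return cfg
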