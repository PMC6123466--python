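"""Gated prognostic screening of mutation carriers.

Per gene: Kaplan-Meier curves and the log-rank (Mantel-Cox) test, a
univariate Cox hazard ratio, and a multivariate Cox model adjusted for node
status (0 vs 1-3 vs 4+), grade (1/2 vs 3) and tumor size category, split at
year 5 into early/late periods. Tests run only when enough carriers exist
(at least 15 for non-silent or missense status, at least 8 for truncating
status). Family-wise multiplicity over the gene panel is controlled by a
min-p permutation procedure: survival outcome and clinical covariates are
jointly permuted against the fixed mutation matrix, all gated genes are
refitted, and a gene's adjusted p is the fraction of permutations in which
the best p-value across genes beats its observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .assoc import MutationMatrix, bh_adjust
from .coxph import CoxEngine, CoxResult, cox_fit, episode_split, split_design
from .errors import ConfigError, ConvergenceError, DegenerateInputError
from .io import ClinicalRecord, SurvivalRecord

#: carrier-count gates per variant-class policy
GATE_BY_POLICY = {"non_silent": 15, "missense": 15,
                  "fs_ns": 8, "fs_ns_splice": 8}


@dataclass
class KMEstimate:
    """Product-limit survival estimate."""

    times: np.ndarray           # distinct event times
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray        # S(t) just after each event time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class PermutationPlan:
    """Settings of the min-p family-wise permutation adjustment."""

    n_permutations: int = 1000
    seed: int = 0
    add_one: bool = False       # optional (1 + count) / (1 + B) estimator

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("need at least one permutation")


@dataclass
class ScreenResult:
    """Per-gene survival screening output."""

    gene: str
    policy: str
    endpoint: str
    n_carriers: int
    gate: str                   # "tested" | "skipped"
    logrank_p: float = float("nan")
    univariate: CoxResult | None = None
    multivariate: CoxResult | None = None
    p: float = float("nan")     # headline p used for q / permutation
    q: float = float("nan")
    adjusted_p: float = float("nan")
    notes: list[str] = field(default_factory=list)


def survival_frame(records: list[SurvivalRecord], endpoint: str,
                   samples: list[str]) -> pd.DataFrame:
    """Align one endpoint's (time, event) with a sample list."""
    by_sample = {r.sample_id: r for r in records if r.endpoint == endpoint}
    missing = [s for s in samples if s not in by_sample]
    if missing:
        raise DegenerateInputError(
            f"{len(missing)} samples lack {endpoint} survival data "
            f"(first: {missing[0]})")
    return pd.DataFrame({
        "time": [by_sample[s].time for s in samples],
        "event": [by_sample[s].event for s in samples]}, index=samples)


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator (censored ranked after events
    at tied times)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise DegenerateInputError("no observations for KM estimate")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    steps = table[table["observed"] > 0]
    ts = steps.index.to_numpy(float)
    surv = np.array([float(kmf.survival_function_.loc[t].iloc[0])
                     for t in ts])
    return KMEstimate(
        times=ts,
        at_risk=steps["at_risk"].to_numpy(int),
        n_events=steps["observed"].to_numpy(int),
        survival=surv,
        censor_times=np.sort(times[events == 0]))


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]]):
    """K-group log-rank (Mantel-Cox) test; returns (chi2, df, p)."""
    if len(groups) < 2:
        raise DegenerateInputError("log-rank needs at least two groups")
    all_t, all_e, all_g = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, float)
        e = np.asarray(e, int)
        if t.size == 0:
            raise DegenerateInputError(f"log-rank group {gi} is empty")
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.full(t.size, gi))
    res = multivariate_logrank_test(np.concatenate(all_t),
                                    np.concatenate(all_g),
                                    np.concatenate(all_e))
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# Clinical covariate coding
# ---------------------------------------------------------------------------

def clinical_design(records: list[ClinicalRecord],
                    samples: list[str],
                    cnv_genes: tuple[str, ...] = ()) -> pd.DataFrame:
    """Covariate codings of the multivariate model.

    Node status 0 vs 1-3 vs 4+ becomes two dummies; grade 3 vs 1/2 one
    binary; tumor size categories 2-4 three dummies against category 1.
    Optional per-gene copy-number flags append as booleans. Samples without
    clinical data are dropped (an error if more than 10% are missing).
    """
    by_sample = {r.sample_id: r for r in records}
    present = [s for s in samples if s in by_sample]
    if len(present) < 0.9 * len(samples):
        raise DegenerateInputError(
            f"clinical covariates available for only {len(present)} of "
            f"{len(samples)} samples (< 90%)")
    rows = []
    for s in present:
        r = by_sample[s]
        row = {
            "nodes_1_3": float(1 <= r.nodes_positive <= 3),
            "nodes_4plus": float(r.nodes_positive >= 4),
            "grade_3": float(r.grade == 3),
            "size_2": float(r.tumor_size_category == 2),
            "size_3": float(r.tumor_size_category == 3),
            "size_4": float(r.tumor_size_category == 4),
        }
        for g in cnv_genes:
            row[f"cnv_{g}"] = float(r.cnv_flags.get(g, False))
        rows.append(row)
    return pd.DataFrame(rows, index=present)


def _gate_for(policy: str) -> int:
    if policy not in GATE_BY_POLICY:
        raise ConfigError(f"no carrier gate defined for policy {policy!r}")
    return GATE_BY_POLICY[policy]


def _gene_headline_p(result: CoxResult, gene_cov: str) -> float:
    """Wald p of the gene's coefficient; for split fits the smaller of the
    early/late period p-values (the same statistic is used for observed and
    permuted fits, so the min-p adjustment stays valid)."""
    ps = [result.p_of(n) for n in result.names
          if n == gene_cov or n.startswith(gene_cov + ":")]
    if not ps:
        return float("nan")
    return float(min(ps))


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def univariate_screen(matrix: MutationMatrix, survival: pd.DataFrame,
                      endpoint: str, ties: str = "efron") -> list[ScreenResult]:
    """Per-gene KM/log-rank and univariate Cox, gated on carrier counts.

    ``survival`` must be indexed by the matrix's samples with columns
    time/event. BH q-values span the log-rank p of tested genes.
    """
    gate = _gate_for(matrix.policy)
    survival = survival.loc[matrix.samples]
    times = survival["time"].to_numpy(float)
    events = survival["event"].to_numpy(int)
    results = []
    for gene in matrix.genes:
        carrier = matrix.carriers(gene)
        n_car = int(carrier.sum())
        res = ScreenResult(gene=gene, policy=matrix.policy,
                           endpoint=endpoint, n_carriers=n_car,
                           gate="tested" if n_car >= gate else "skipped")
        if res.gate == "skipped":
            results.append(res)
            continue
        try:
            _, _, res.logrank_p = logrank_test(
                [(times[carrier], events[carrier]),
                 (times[~carrier], events[~carrier])])
        except DegenerateInputError as exc:
            res.notes.append(f"logrank: {exc}")
        try:
            res.univariate = cox_fit(carrier.astype(float), times, events,
                                     names=[gene], ties=ties)
            res.p = res.univariate.p_of(gene)
        except (DegenerateInputError, ConvergenceError) as exc:
            res.notes.append(f"cox: {exc}")
        results.append(res)
    _attach_bh(results, use="logrank")
    return results


def multivariate_screen(matrix: MutationMatrix, survival: pd.DataFrame,
                        clinical: list[ClinicalRecord], endpoint: str,
                        split_at: float | None = 5.0,
                        ties: str = "efron",
                        cnv_genes: tuple[str, ...] = ()) -> list[ScreenResult]:
    """Per-gene Cox adjusted for clinical covariates, split at year 5."""
    gate = _gate_for(matrix.policy)
    design = clinical_design(clinical, matrix.samples, cnv_genes=cnv_genes)
    samples = list(design.index)
    survival = survival.loc[samples]
    times = survival["time"].to_numpy(float)
    events = survival["event"].to_numpy(int)
    data = matrix.data.loc[samples]
    results = []
    for gene in matrix.genes:
        carrier = data[gene].to_numpy()
        n_car = int(carrier.sum())
        res = ScreenResult(gene=gene, policy=matrix.policy,
                           endpoint=endpoint, n_carriers=n_car,
                           gate="tested" if n_car >= gate else "skipped")
        if res.gate == "skipped":
            results.append(res)
            continue
        X = np.column_stack([carrier.astype(float),
                             design.to_numpy(float)])
        names = [gene] + list(design.columns)
        try:
            res.multivariate = cox_fit(X, times, events, names=names,
                                       ties=ties, split_at=split_at)
            res.p = _gene_headline_p(res.multivariate, gene)
        except (DegenerateInputError, ConvergenceError) as exc:
            res.notes.append(f"cox: {exc}")
        results.append(res)
    _attach_bh(results, use="p")
    return results


def _attach_bh(results: list[ScreenResult], use: str) -> None:
    tested = [r for r in results
              if r.gate == "tested"
              and np.isfinite(r.logrank_p if use == "logrank" else r.p)]
    if not tested:
        return
    ps = [r.logrank_p if use == "logrank" else r.p for r in tested]
    for r, q in zip(tested, bh_adjust(ps)):
        r.q = float(q)


# ---------------------------------------------------------------------------
# Min-p permutation adjustment
# ---------------------------------------------------------------------------

def permutation_adjust(results: list[ScreenResult], matrix: MutationMatrix,
                       survival: pd.DataFrame,
                       clinical: list[ClinicalRecord] | None,
                       plan: PermutationPlan,
                       split_at: float | None = 5.0,
                       ties: str = "efron") -> dict[str, float]:
    """Family-wise min-p adjustment over the gated genes.

    Each permutation jointly reshuffles (survival outcome + clinical rows)
    against the fixed mutation matrix — implemented by permuting the carrier
    columns with the inverse reassignment, which yields the identical fit —
    refits every gated gene with the same model specification, and records
    the minimum p across genes. A gene's adjusted p is the proportion of
    permutations whose minimum beats (<=) its observed p; fits that fail in
    a permutation contribute p = 1 for that permutation. The estimate is
    clamped from below by the observed p, which the population quantity
    P(min-p <= p_obs) can never undercut.
    """
    plan.validate()
    tested = [r for r in results if r.gate == "tested" and np.isfinite(r.p)]
    if not tested:
        return {}
    genes = [r.gene for r in tested]
    observed = np.array([r.p for r in tested])

    if clinical is not None:
        design = clinical_design(clinical, matrix.samples)
        samples = list(design.index)
        clin_X = design.to_numpy(float)
        clin_names = list(design.columns)
    else:
        samples = matrix.samples
        clin_X = np.empty((len(samples), 0))
        clin_names = []
    survival = survival.loc[samples]
    times = survival["time"].to_numpy(float)
    events = survival["event"].to_numpy(int)
    mut = matrix.data.loc[samples].to_numpy(float)
    gene_idx = {g: matrix.genes.index(g) for g in genes}
    n = len(samples)

    # risk-set structure and the clinical design block are permutation-free
    if split_at is not None:
        entry, stop, ev, subject, late = episode_split(times, events,
                                                       split_at)
        engine = CoxEngine(stop, ev, entry=entry, ties=ties)
        clin_block, clin_block_names = (
            split_design(clin_X, clin_names, subject, late)
            if clin_names else (np.empty((stop.size, 0)), []))

        def fit_gene(col: np.ndarray) -> float:
            gX, gnames = split_design(col[:, None], ["g"], subject, late)
            X = np.hstack([gX, clin_block])
            names = gnames + clin_block_names
            spans = X.max(axis=0) - X.min(axis=0)
            keep = spans > 0
            if not keep[:gX.shape[1]].any():
                return 1.0
            try:
                fit = engine.fit(X[:, keep],
                                 names=[nm for nm, k in zip(names, keep)
                                        if k])
            except (DegenerateInputError, ConvergenceError):
                return 1.0
            return _gene_headline_p(fit, "g")
    else:
        engine = CoxEngine(times, events, ties=ties)

        def fit_gene(col: np.ndarray) -> float:
            X = np.column_stack([col, clin_X]) if clin_names else col[:, None]
            try:
                fit = engine.fit(X, names=["g"] + clin_names)
            except (DegenerateInputError, ConvergenceError):
                return 1.0
            return fit.p_of("g")

    rng = np.random.default_rng(plan.seed)
    min_p = np.empty(plan.n_permutations)
    for b in range(plan.n_permutations):
        perm = rng.permutation(n)
        ps = [fit_gene(mut[perm, gene_idx[g]]) for g in genes]
        min_p[b] = min(ps)

    counts = (min_p[:, None] <= observed[None, :]).sum(axis=0)
    if plan.add_one:
        adjusted = (1.0 + counts) / (1.0 + plan.n_permutations)
    else:
        adjusted = counts / plan.n_permutations
    adjusted = np.maximum(adjusted, observed)
    out = {}
    for r, adj in zip(tested, adjusted):
        r.adjusted_p = float(min(adj, 1.0))
        out[r.gene] = r.adjusted_p
    return out


# ---------------------------------------------------------------------------
# Two-gene interaction
# ---------------------------------------------------------------------------

def two_gene_analysis(matrix: MutationMatrix, survival: pd.DataFrame,
                      gene_a: str = "MAP3K1", gene_b: str = "PIK3CA") -> dict:
    """Four-group survival comparison: both / A-only / B-only / neither.

    Empty groups are dropped with a warning and the log-rank df reduced.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.genes:
            raise DegenerateInputError(f"gene {g} not in mutation matrix")
    a = matrix.carriers(gene_a)
    b = matrix.carriers(gene_b)
    if not a.any() and not b.any():
        raise DegenerateInputError(
            f"neither {gene_a} nor {gene_b} has any carrier")
    survival = survival.loc[matrix.samples]
    times = survival["time"].to_numpy(float)
    events = survival["event"].to_numpy(int)
    masks = {
        "both": a & b,
        f"{gene_a}_only": a & ~b,
        f"{gene_b}_only": ~a & b,
        "neither": ~a & ~b,
    }
    groups, km, labels = [], {}, {}
    for name, mask in masks.items():
        n = int(mask.sum())
        labels[name] = n
        if n == 0:
            warnings.warn(f"two-gene analysis: group {name!r} is empty; "
                          "dropped from the log-rank test")
            continue
        groups.append((times[mask], events[mask]))
        km[name] = km_estimate(times[mask], events[mask])
    chi2, df, p = logrank_test(groups)
    return {"group_sizes": labels, "km": km, "chi2": chi2, "df": df, "p": p}


def screen_results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Forest-plot-shaped TSV table of screen results."""
    rows = []
    for r in results:
        row = {"gene": r.gene, "policy": r.policy, "endpoint": r.endpoint,
               "n_carriers": r.n_carriers, "gate": r.gate,
               "logrank_p": r.logrank_p, "p": r.p, "q": r.q,
               "adjusted_p": r.adjusted_p,
               "hr": float("nan"), "ci_low": float("nan"),
               "ci_high": float("nan"),
               "hr_early": float("nan"), "hr_late": float("nan")}
        fit = r.univariate or r.multivariate
        if r.univariate is not None and r.gene in r.univariate.names:
            i = r.univariate.names.index(r.gene)
            lo, hi = r.univariate.ci
            row.update(hr=float(r.univariate.hazard_ratio[i]),
                       ci_low=float(lo[i]), ci_high=float(hi[i]))
        if r.multivariate is not None:
            names = r.multivariate.names
            for suffix, col in (("early", "hr_early"), ("late", "hr_late")):
                nm = f"{r.gene}:{suffix}"
                if nm in names:
                    i = names.index(nm)
                    row[col] = float(r.multivariate.hazard_ratio[i])
            if r.gene in names and fit is r.multivariate:
                i = names.index(r.gene)
                lo, hi = r.multivariate.ci
                row.update(hr=float(r.multivariate.hazard_ratio[i]),
                           ci_low=float(lo[i]), ci_high=float(hi[i]))
        rows.append(row)
    return pd.DataFrame(rows)
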