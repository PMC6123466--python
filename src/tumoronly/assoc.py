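"""Mutation-covariate association testing.

Carrier status under a variant-class policy is crossed with categorical
covariates (intrinsic subtype, receptor status) by Fisher's exact or
chi-squared tests, with continuous covariates (age, node counts) by t-test
or Mann-Whitney U according to a Kolmogorov-Smirnov normality check, and
pairwise co-occurrence / mutual exclusivity is screened among the most
recurrently mutated genes. Benjamini-Hochberg q-values are reported per
test family; a reportability threshold (q < 0.2 by default) is a label in
the output, never a filter.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError
from .filters import ClassPolicy
from .io import VariantRecord


@dataclass
class MutationMatrix:
    """Sample x gene boolean carrier matrix under a named class policy."""

    data: pd.DataFrame          # index: sample ids; columns: genes; bool
    policy: str

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def carriers(self, gene: str) -> np.ndarray:
        return self.data[gene].to_numpy()

    def carrier_counts(self) -> pd.Series:
        return self.data.sum(axis=0).sort_values(ascending=False)


@dataclass
class AssociationResult:
    gene: str
    policy: str
    covariate: str
    test: str                   # fisher | chi2 | ttest | mannwhitney
    statistic: float
    p: float
    q: float = float("nan")
    effect: float | dict | None = None
    direction: str = ""


def build_mutation_matrix(variants: list[VariantRecord],
                          samples: list[str],
                          policy: ClassPolicy,
                          genes: list[str] | None = None) -> MutationMatrix:
    """Carrier matrix: True iff the sample has >= 1 qualifying variant in the
    gene. Samples with no variants appear as all-False rows."""
    sample_set = set(samples)
    if genes is None:
        genes = sorted({v.gene for v in variants})
    data = pd.DataFrame(False, index=list(samples), columns=list(genes))
    for v in variants:
        if v.sample_id not in sample_set:
            raise ValidationError(
                f"variant sample {v.sample_id!r} not in sample list")
        if policy.includes(v) and v.gene in data.columns:
            data.loc[v.sample_id, v.gene] = True
    return MutationMatrix(data=data, policy=policy.name)


# ---------------------------------------------------------------------------
# Categorical tests
# ---------------------------------------------------------------------------

def _mc_conditional_p(table: np.ndarray, n_draws: int = 20000) -> float:
    """Monte-Carlo conditional test for r x c tables too sparse for the
    chi-squared approximation and too large for exact enumeration.

    Labels are permuted against carrier status (conditioning on both
    margins); the p-value is the fraction of permuted tables whose Pearson
    statistic reaches the observed one. The stream is seeded from the table
    itself so results are deterministic and order-free.
    """
    seed = int.from_bytes(
        hashlib.sha256(np.ascontiguousarray(table).tobytes()).digest()[:4],
        "little")
    rng = np.random.default_rng(seed)
    obs_stat = stats.chi2_contingency(table, correction=False)[0]
    row_labels = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    col_counts = table.sum(axis=0)
    hits = 0
    r, c = table.shape
    for _ in range(n_draws):
        perm = rng.permutation(row_labels)
        t = np.zeros((r, c))
        start = 0
        for j, n_j in enumerate(col_counts):
            seg = perm[start:start + n_j]
            t[:, j] = np.bincount(seg, minlength=r)
            start += n_j
        with np.errstate(divide="ignore", invalid="ignore"):
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            statv = np.nansum((t - exp) ** 2 / exp)
        if statv >= obs_stat - 1e-12:
            hits += 1
    return max(hits / n_draws, 1.0 / n_draws)


def test_categorical_association(carrier: np.ndarray,
                                 labels: np.ndarray,
                                 gene: str = "", policy: str = "",
                                 covariate: str = "") -> AssociationResult:
    """Carrier status vs a categorical covariate.

    2x2 tables always use Fisher's exact test (two-sided, with the odds
    ratio); larger tables use chi-squared unless any expected cell is below
    5, in which case a seeded Monte-Carlo conditional test replaces the
    asymptotic approximation.
    """
    carrier = np.asarray(carrier, bool)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise DegenerateInputError(
            "categorical covariate has a single level")
    table = np.array([[(carrier & (labels == lv)).sum() for lv in levels],
                      [(~carrier & (labels == lv)).sum() for lv in levels]])
    if table.shape == (2, 2):
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        direction = ("enriched" if np.isinf(odds) or odds > 1
                     else "depleted" if odds < 1 else "")
        return AssociationResult(gene=gene, policy=policy,
                                 covariate=covariate, test="fisher",
                                 statistic=float(odds), p=float(p),
                                 effect=float(odds), direction=direction)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        p = _mc_conditional_p(table)
        test = "fisher"         # exact-conditional branch of the rule
    else:
        test = "chi2"
    return AssociationResult(gene=gene, policy=policy, covariate=covariate,
                             test=test, statistic=float(chi2), p=float(p))


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]] (minimum-likelihood
    convention); returns (odds ratio, p)."""
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def pairwise_cooccurrence(matrix: MutationMatrix,
                          top_k: int = 7) -> list[AssociationResult]:
    """Co-occurrence / mutual exclusivity among the most-mutated genes.

    All unordered pairs of the ``top_k`` genes with the highest carrier
    counts are tested (2x2 Fisher); direction follows the odds ratio; BH
    adjustment spans the tested pairs.
    """
    if len(matrix.genes) < 2:
        raise DegenerateInputError("need at least two genes")
    counts = matrix.carrier_counts()
    # deterministic top-k: count descending, then gene name
    order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [g for g, _ in order[:top_k]]
    results = []
    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            a = matrix.carriers(top[i])
            b = matrix.carriers(top[j])
            both = int((a & b).sum())
            only_a = int((a & ~b).sum())
            only_b = int((~a & b).sum())
            neither = int((~a & ~b).sum())
            odds, p = fisher_2x2(both, only_a, only_b, neither)
            direction = "co-occurring" if odds > 1 else "exclusive"
            results.append(AssociationResult(
                gene=f"{top[i]}|{top[j]}", policy=matrix.policy,
                covariate="cooccurrence", test="fisher",
                statistic=float(odds), p=float(p), effect=float(odds),
                direction=direction))
    attach_q(results)
    return results


# ---------------------------------------------------------------------------
# Continuous tests
# ---------------------------------------------------------------------------

def test_continuous_association(group_a: np.ndarray, group_b: np.ndarray,
                                gene: str = "", policy: str = "",
                                covariate: str = "",
                                ks_alpha: float = 0.05,
                                method: str = "auto") -> AssociationResult:
    """Two-group comparison of a continuous covariate.

    With ``method='auto'``, each group is checked against a fitted normal by
    the Kolmogorov-Smirnov test; the Welch t-test is used when both groups
    are consistent with normality (p >= ``ks_alpha``), otherwise the
    Mann-Whitney U test. Group medians are reported as the effect summary.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each group needs >= 2 observations")
    if method == "auto":
        normal = []
        for g in (a, b):
            sd = g.std(ddof=1)
            if sd == 0:
                normal.append(False)
                continue
            p_ks = stats.kstest(g, "norm", args=(g.mean(), sd)).pvalue
            normal.append(p_ks >= ks_alpha)
        method = "ttest" if all(normal) else "mannwhitney"
    if method == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValidationError(f"unknown method {method!r}")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = ("higher" if med_a > med_b
                 else "lower" if med_a < med_b else "")
    return AssociationResult(gene=gene, policy=policy, covariate=covariate,
                             test=method, statistic=statistic, p=p,
                             effect={"median_a": med_a, "median_b": med_b},
                             direction=direction)


# ---------------------------------------------------------------------------
# VAF-based germline suspicion
# ---------------------------------------------------------------------------

def vaf_germline_suspicion(variants: list[VariantRecord],
                           flagged_genes: tuple[str, ...] = ("BRCA1", "BRCA2",
                                                             "ATM"),
                           ks_alpha: float = 0.05) -> dict:
    """Flag genes whose variants sit at germline-like allele fractions.

    In impure tumors a clonal heterozygous somatic variant is expected well
    below VAF 0.5, so an excess of variants above 40% (and especially 60%)
    in cancer-predisposition genes suggests unfiltered germline mutations.
    Counts are strictly greater-than; the mean-VAF comparison against all
    other genes uses the continuous-test rule.
    """
    flagged = set(flagged_genes)
    report: dict = {"per_gene": {}, "flagged_genes": sorted(flagged)}
    flagged_vafs, other_vafs = [], []
    for gene in sorted(flagged):
        vafs = [v.vaf for v in variants if v.gene == gene]
        report["per_gene"][gene] = {
            "n_variants": len(vafs),
            "n_vaf_gt_40": sum(1 for x in vafs if x > 0.40),
            "n_vaf_gt_60": sum(1 for x in vafs if x > 0.60),
            "mean_vaf": float(np.mean(vafs)) if vafs else float("nan"),
        }
    for v in variants:
        (flagged_vafs if v.gene in flagged else other_vafs).append(v.vaf)
    report["mean_vaf_flagged"] = (float(np.mean(flagged_vafs))
                                  if flagged_vafs else float("nan"))
    report["mean_vaf_other"] = (float(np.mean(other_vafs))
                                if other_vafs else float("nan"))
    if len(flagged_vafs) >= 2 and len(other_vafs) >= 2:
        res = test_continuous_association(
            np.array(flagged_vafs), np.array(other_vafs),
            covariate="vaf", ks_alpha=ks_alpha)
        report["test"] = res.test
        report["p"] = res.p
        report["direction"] = res.direction
    return report


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q(results: list[AssociationResult]) -> None:
    """BH-adjust in place across one family of association results."""
    if not results:
        return
    q = bh_adjust([r.p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)


def results_frame(results: list[AssociationResult],
                  reportable_q: float = 0.2) -> pd.DataFrame:
    rows = [{"gene": r.gene, "policy": r.policy, "covariate": r.covariate,
             "test": r.test, "statistic": r.statistic, "p": r.p, "q": r.q,
             "effect": (r.effect if not isinstance(r.effect, dict)
                        else str(r.effect)),
             "direction": r.direction,
             "reportable": bool(r.q < reportable_q)} for r in results]
    return pd.DataFrame(rows, columns=["gene", "policy", "covariate", "test",
                                       "statistic", "p", "q", "effect",
                                       "direction", "reportable"])
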