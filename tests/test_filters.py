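"""Filtering cascade: boundary semantics, the LLR classifier, and
equivalence with an independent rule-by-rule oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from tumoronly.config import FilterThresholds
from tumoronly.errors import ConfigError, PipelineError, ValidationError
from tumoronly.filters import (KnowledgeBaseSite, ReferencePanels,
                               assign_class_sets, binomial_llr,
                               classify_somatic_llr,
                               filter_population_frequency,
                               filter_readcount_panel,
                               filter_unmatched_normal_calls, get_policy,
                               mutations_per_mb, burden_summary,
                               rescue_known_hotspots, restrict_to_targets,
                               run_filter_cascade, sample_coverage_qc)
from tumoronly.io import TargetRegion, VariantRecord

THR = FilterThresholds()


def make_variant(chrom="1", pos=100, ref="A", alt="G", var_reads=30,
                 depth=100, vtype="SNV", cls="missense", gene="G1",
                 sample="S1", protein_change="A10V"):
    return VariantRecord(sample_id=sample, gene=gene, chrom=chrom, pos=pos,
                         ref=ref, alt=alt, variant_type=vtype,
                         consequence_class=cls, var_reads=var_reads,
                         depth=depth, protein_change=protein_change)


def empty_panels(**kw):
    base = dict(population_maf={}, normal_call_counts={},
                exome_readcount_panel={}, genome_readcount_panel={})
    base.update(kw)
    return ReferencePanels(**base)


class TestTargetRestriction:
    REGIONS = [TargetRegion("1", 100, 200, "G1"),
               TargetRegion("2", 50, 60, "G2")]

    def test_boundaries_inclusive(self):
        kept = restrict_to_targets(
            [make_variant(pos=100), make_variant(pos=200),
             make_variant(pos=201), make_variant(pos=99)], self.REGIONS)
        assert [v.pos for v in kept] == [100, 200]

    def test_matches_brute_force_interval_check(self, rng):
        variants = [make_variant(chrom=str(rng.integers(1, 4)),
                                 pos=int(rng.integers(1, 300)))
                    for _ in range(50)]
        kept = restrict_to_targets(variants, self.REGIONS)
        expect = [v for v in variants
                  if any(r.chrom == v.chrom and r.start <= v.pos <= r.end
                         for r in self.REGIONS)]
        assert kept == expect

    def test_empty_region_set_is_error(self):
        with pytest.raises(ConfigError):
            restrict_to_targets([make_variant()], [])


class TestPopulationFilter:
    def test_strictly_greater_rule(self):
        panels = empty_panels(population_maf={
            ("1", 100, "A", "G"): (0.002, 0.0, 0.0),
            ("1", 101, "A", "G"): (0.001, 0.001, 0.001)})
        variants = [make_variant(pos=100), make_variant(pos=101),
                    make_variant(pos=102)]
        kept, trace = filter_population_frequency(variants, panels, THR)
        # 0.2% in any one resource removes; exactly 0.1% and absent retain
        assert [v.pos for v in kept] == [101, 102]
        assert [t[0] for t in trace] == [False, True, True]


class TestUnmatchedNormalFilter:
    @pytest.mark.parametrize("count,kept", [(10, False), (9, True),
                                            (0, True)])
    def test_boundary_at_ten(self, count, kept):
        panels = empty_panels(
            normal_call_counts={("1", 100, "A", "G"): count})
        out, _ = filter_unmatched_normal_calls([make_variant()], panels, THR)
        assert bool(out) is kept


class TestReadcountPanels:
    def _panels(self, n_evidence, mode):
        obs = [(5, 100)] * n_evidence          # qualifying evidence
        key = ("1", 100, "A", "G")
        if mode == "exome":
            return empty_panels(exome_readcount_panel={key: obs})
        return empty_panels(genome_readcount_panel={key: obs})

    def test_exome_fraction_boundary(self):
        # 10/912 = 1.096% removes; 9/912 = 0.987% retains
        out, _ = filter_readcount_panel([make_variant()],
                                        self._panels(10, "exome"),
                                        "exome", THR)
        assert not out
        out, _ = filter_readcount_panel([make_variant()],
                                        self._panels(9, "exome"),
                                        "exome", THR)
        assert out

    def test_genome_count_boundary(self):
        out, _ = filter_readcount_panel([make_variant()],
                                        self._panels(2, "genome"),
                                        "genome", THR)
        assert not out

    def test_low_vaf_sample_is_not_evidence(self):
        # var_reads=3 at depth 400 is 0.75% VAF: below the 1% evidence rule
        key = ("1", 100, "A", "G")
        panels = empty_panels(genome_readcount_panel={
            key: [(3, 400), (3, 400), (3, 400)]})
        out, trace = filter_readcount_panel([make_variant()], panels,
                                            "genome", THR)
        assert out and trace[0][1] == 0

    def test_unknown_mode_is_error(self):
        with pytest.raises(ConfigError):
            filter_readcount_panel([make_variant()], empty_panels(),
                                   "transcriptome", THR)


class TestLLRClassifier:
    def test_matches_direct_log_pmf_ratio(self):
        # oracle: difference of binomial log-pmfs at the MLE and the null
        thr = FilterThresholds(p_err=0.01)
        for x, n in [(8, 100), (9, 100), (0, 50), (50, 50), (3, 230)]:
            oracle = (binom.logpmf(x, n, max(x / n, 1e-300))
                      - binom.logpmf(x, n, thr.p_err))
            assert binomial_llr(x, n, thr.p_err) == pytest.approx(
                oracle, abs=1e-9)

    def test_decision_boundary_x8_vs_x9_at_n100(self):
        thr = FilterThresholds(p_err=0.01)
        llr8, keep8 = classify_somatic_llr(make_variant(var_reads=8,
                                                        depth=100), thr)
        llr9, keep9 = classify_somatic_llr(make_variant(var_reads=9,
                                                        depth=100), thr)
        assert llr8 < 10 < llr9
        assert (keep8, keep9) == (False, True)

    def test_no_supporting_reads_removed(self):
        llr, keep = classify_somatic_llr(make_variant(var_reads=0,
                                                      depth=100), THR)
        assert llr == pytest.approx(-100 * math.log(1 - THR.p_err))
        assert not keep

    def test_exact_threshold_is_kept(self):
        # removal is strictly "less than"; manufacture an exact tie
        thr = FilterThresholds(llr_snv=binomial_llr(9, 100, THR.p_err))
        _, keep = classify_somatic_llr(make_variant(var_reads=9, depth=100),
                                       thr)
        assert keep

    def test_indel_threshold_is_six(self):
        v = make_variant(var_reads=4, depth=150, vtype="DEL", ref="AT",
                         alt="A", cls="frameshift")
        llr, keep = classify_somatic_llr(v, THR)
        assert keep == (llr >= 6)

    def test_zero_depth_is_error(self):
        with pytest.raises(ValidationError):
            binomial_llr(0, 0, 0.005)

    @given(n=st.integers(1, 10000), frac=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_identity_with_pmf_ratio_everywhere(self, n, frac):
        x = int(round(frac * n))
        direct = (binom.logpmf(x, n, max(min(x / n, 1 - 1e-16), 1e-300))
                  - binom.logpmf(x, n, 0.005))
        assert binomial_llr(x, n, 0.005) == pytest.approx(direct, abs=1e-9)

    @given(n=st.integers(10, 5000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_x_above_error_rate(self, n):
        xs = [x for x in range(n + 1) if x / n >= 0.005]
        vals = [binomial_llr(x, n, 0.005) for x in xs[:: max(1, n // 40)]]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestRescue:
    KB = [KnowledgeBaseSite("3", 178952085, "A", "G", "PIK3CA", "H1047R")]

    def test_vaf_boundary_exactly_one_percent_called(self):
        calls = rescue_known_hotspots(
            {("S1", ("3", 178952085, "A", "G")): (5, 500)}, self.KB, THR)
        assert len(calls) == 1 and calls[0].protein_change == "H1047R"

    def test_four_reads_not_called(self):
        calls = rescue_known_hotspots(
            {("S1", ("3", 178952085, "A", "G")): (4, 20)}, self.KB, THR)
        assert calls == []

    def test_site_absent_from_knowledge_base_ignored(self):
        calls = rescue_known_hotspots(
            {("S1", ("9", 5, "A", "T")): (50, 100)}, self.KB, THR)
        assert calls == []


class TestClassPolicies:
    def test_non_silent_membership(self):
        policy = get_policy("non_silent")
        assert not policy.includes(make_variant(cls="silent"))
        assert not policy.includes(make_variant(cls="splice_region"))
        assert policy.includes(make_variant(cls="splice_site"))
        assert policy.includes(make_variant(cls="rna", gene="MALAT1"))
        assert not policy.includes(make_variant(cls="rna", gene="XIST"))

    def test_policy_nesting(self):
        fs_ns = get_policy("fs_ns")
        fs_ns_splice = get_policy("fs_ns_splice")
        non_silent = get_policy("non_silent")
        assert fs_ns.classes < fs_ns_splice.classes < non_silent.classes

    def test_unknown_policy_is_error(self):
        with pytest.raises(ConfigError):
            get_policy("pathogenic")

    def test_assign_class_sets_subsets(self):
        variants = [make_variant(cls=c) for c in
                    ("missense", "nonsense", "silent", "frameshift",
                     "intron")]
        got = assign_class_sets(variants, get_policy("fs_ns"))
        assert [v.consequence_class for v in got] == ["nonsense",
                                                      "frameshift"]


def cascade_oracle(variants, panels, kb, thr):
    """Independent rule-by-rule reimplementation of the cascade verdicts."""
    kb_keys = {s.key for s in kb}
    retained = []
    for v in variants:
        mafs = panels.population_maf.get(v.key, (0.0, 0.0, 0.0))
        fails = max(mafs) > thr.pop_maf_max
        if panels.normal_call_counts.get(v.key, 0) >= thr.normal_call_min:
            fails = True
        for panel, size, rule in (
                (panels.exome_readcount_panel, panels.n_exome_panel, "frac"),
                (panels.genome_readcount_panel, panels.n_genome_panel,
                 "count")):
            n_ev = 0
            for vr, dp in panel.get(v.key, []):
                if (dp > 0 and vr >= thr.panel_min_var_reads
                        and vr / dp >= thr.panel_min_vaf
                        and dp >= thr.panel_min_depth):
                    n_ev += 1
            if rule == "frac" and n_ev / size >= thr.exome_panel_frac:
                fails = True
            if rule == "count" and n_ev >= thr.genome_panel_count:
                fails = True
        p_hat = v.var_reads / v.depth
        llr = 0.0
        if v.var_reads:
            llr += v.var_reads * math.log(p_hat / thr.p_err)
        if v.var_reads < v.depth:
            llr += (v.depth - v.var_reads) * math.log(
                (1 - p_hat) / (1 - thr.p_err))
        cutoff = thr.llr_indel if v.variant_type in ("INS", "DEL") \
            else thr.llr_snv
        if llr < cutoff:
            fails = True
        rescued = (v.key in kb_keys
                   and v.var_reads >= thr.rescue_min_var_reads
                   and p_hat >= thr.rescue_min_vaf
                   and v.depth >= thr.rescue_min_depth)
        if not fails or rescued:
            retained.append((v.sample_id, v.key))
    return retained


class TestCascade:
    def _random_setup(self, rng, n=1000):
        variants, pop, normals, exome, genome = [], {}, {}, {}, {}
        kb = []
        for i in range(n):
            key = ("1", i + 1, "A", "G")
            depth = int(rng.integers(20, 400))
            var_reads = int(rng.integers(0, depth + 1))
            vtype = "SNV" if rng.random() < 0.8 else "DEL"
            variants.append(make_variant(
                pos=i + 1, var_reads=var_reads, depth=depth, vtype=vtype,
                ref="AT" if vtype == "DEL" else "A",
                alt="A" if vtype == "DEL" else "G",
                cls="frameshift" if vtype == "DEL" else "missense",
                sample=f"S{rng.integers(5)}"))
            if rng.random() < 0.3:
                pop[key] = tuple(
                    float(rng.choice([0.0, 0.0005, 0.001, 0.002, 0.05]))
                    for _ in range(3))
            if rng.random() < 0.3:
                normals[key] = int(rng.integers(0, 30))
            if rng.random() < 0.3:
                exome[key] = [(int(rng.integers(0, 10)),
                               int(rng.integers(1, 200)))
                              for _ in range(int(rng.integers(0, 20)))]
            if rng.random() < 0.3:
                genome[key] = [(int(rng.integers(0, 10)),
                                int(rng.integers(1, 200)))
                               for _ in range(int(rng.integers(0, 4)))]
            if rng.random() < 0.05:
                kb.append(KnowledgeBaseSite("1", i + 1, variants[-1].ref,
                                            variants[-1].alt, "G1", "X1X"))
        panels = empty_panels(population_maf=pop, normal_call_counts=normals,
                              exome_readcount_panel=exome,
                              genome_readcount_panel=genome)
        return variants, panels, kb

    def test_cascade_equals_independent_oracle(self, rng):
        variants, panels, kb = self._random_setup(rng)
        retained, trace, summary = run_filter_cascade(variants, panels, kb,
                                                      THR)
        got = [(v.sample_id, v.key) for v in retained]
        assert got == cascade_oracle(variants, panels, kb, THR)

    def test_trace_covers_every_stage_for_every_variant(self, rng):
        variants, panels, kb = self._random_setup(rng, n=50)
        _, trace, _ = run_filter_cascade(variants, panels, kb, THR)
        per_variant = trace.groupby(["sample_id", "chrom", "pos", "ref",
                                     "alt"])["stage"].nunique()
        assert (per_variant == 5).all()

    def test_rescued_variant_failing_llr_has_rescued_status(self):
        kb = [KnowledgeBaseSite("1", 100, "A", "G", "G1", "X1X")]
        v = make_variant(var_reads=5, depth=100)   # LLR ~ below 10
        assert classify_somatic_llr(v, THR)[1] is False
        retained, _, summary = run_filter_cascade([v], empty_panels(), kb,
                                                  THR)
        assert retained == [v] and summary["rescued"] == 1

    def test_germline_above_threshold_removed_on_synthetic(self,
                                                           small_cohort):
        cfg, data, panels, _ = small_cohort
        retained, _, _ = run_filter_cascade(
            data.variants, panels, [], FilterThresholds(),
            regions=data.regions)
        kept = {(v.sample_id, v.key) for v in retained}
        for v in data.variants:
            if data.truth.label_of(v) != "germline":
                continue
            maf = max(panels.population_maf.get(v.key, (0.0,)))
            if maf > 0.001:
                assert (v.sample_id, v.key) not in kept


class TestTruthRecoveryStability:
    def test_somatic_retention_and_artifact_removal_across_seeds(self):
        """Cascade performance against truth labels is high and stable
        across generator seeds (within Monte-Carlo variation)."""
        from tumoronly.synth import CohortGenerator, GeneratorConfig
        for seed in (101, 202):
            gen = CohortGenerator(GeneratorConfig(n_samples=150, seed=seed))
            data = gen.generate_cohort()
            panels = gen.generate_reference_panels()
            retained, _, _ = run_filter_cascade(
                data.variants, panels, [], FilterThresholds(),
                regions=data.regions)
            kept = {(v.sample_id, v.key) for v in retained}
            by_label = {"somatic": [0, 0], "artifact": [0, 0]}
            for v in data.variants:
                label = data.truth.label_of(v)
                if label in by_label:
                    by_label[label][(v.sample_id, v.key) in kept] += 1
            som_removed, som_kept = by_label["somatic"]
            art_removed, art_kept = by_label["artifact"]
            assert som_kept / (som_kept + som_removed) > 0.9
            assert art_removed / (art_removed + art_kept) > 0.95


class TestQCAndBurden:
    def test_qc_boundary(self):
        result = sample_coverage_qc({"A": 0.80, "B": 0.799, "C": 0.95}, THR)
        assert result == {"A": True, "B": False, "C": True}

    def test_all_failing_is_pipeline_error(self):
        with pytest.raises(PipelineError, match="no analyzable"):
            sample_coverage_qc({"A": 0.5, "B": 0.6}, THR)

    def test_mutations_per_mb_worked_value(self):
        assert mutations_per_mb(1, 362_572) == pytest.approx(2.758, abs=5e-4)

    def test_correction_scales_linearly(self):
        base = mutations_per_mb(7, 362_572)
        assert mutations_per_mb(7, 362_572, 1.5) == pytest.approx(1.5 * base)

    def test_zero_mutation_samples_excluded_from_range(self):
        summary = burden_summary({"A": 0, "B": 2}, 1_000_000)
        assert summary["excluded_zero_mutation"] == ["A"]
        assert summary["min"] == summary["max"] == pytest.approx(2.0)
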