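import pytest

from ffpesoma.filtering import (
    CohortCalls,
    apply_replicate_consensus,
    classify_oxidation,
    filter_indels,
    is_high_confidence,
    population_filter,
    recurrent_artifact_filter,
    run_filter_cascade,
)
from ffpesoma.model import (
    FILTER_OXIDATION,
    FILTER_POPULATION,
    FILTER_RECURRENT,
    FILTER_RESCUED,
    CallerRole,
    FilterConfig,
    GenomicVariant,
    PopulationFrequencyTable,
    SampleMeta,
)
from helpers import make_call

CFG = FilterConfig()


class TestOxidationFilter:
    @pytest.mark.parametrize("ref,alt,vaf,context,expected", [
        ("C", "A", 0.08, "CCA", True),
        ("C", "A", 0.10, "TCT", True),   # <= is inclusive at the boundary
        ("C", "A", 0.11, "TCT", False),  # just above the VAF window
        ("C", "A", 0.08, "ACA", False),  # context mismatch
        ("G", "T", 0.05, "AGG", True),   # reverse-strand clause
        ("G", "T", 0.05, "AGA", True),
        ("G", "T", 0.05, "AGC", False),
        ("C", "T", 0.05, "CCA", False),  # wrong substitution type
    ])
    def test_rule(self, ref, alt, vaf, context, expected):
        call = make_call(ref=ref, alt=alt, vaf=vaf)
        assert classify_oxidation(call, context, CFG) is expected

    def test_not_applicable_cases(self):
        mnv = make_call(ref="CC", alt="TT", vaf=0.05)
        assert classify_oxidation(mnv, "ACC", CFG) is None
        snv = make_call(ref="C", alt="A", vaf=0.05)
        assert classify_oxidation(snv, None, CFG) is None

    def test_context_must_center_on_ref(self):
        call = make_call(ref="C", alt="A", vaf=0.05)
        with pytest.raises(ValueError):
            classify_oxidation(call, "AAA", CFG)


class TestHighConfidence:
    @pytest.mark.parametrize("ref,alt,alt_depth,vaf,expected", [
        ("C", "T", 10, 0.051, True),
        ("C", "T", 10, 0.050, False),  # strict > on the C>T VAF bar
        ("C", "T", 9, 0.30, False),    # read-count bar
        ("G", "A", 10, 0.050, False),  # strand-symmetric C>T rule
        ("A", "G", 8, 0.040, True),    # inclusive >= for other types
        ("A", "G", 7, 0.30, False),
        ("A", "G", 8, 0.039, False),
    ])
    def test_rule(self, ref, alt, alt_depth, vaf, expected):
        call = make_call(ref=ref, alt=alt, alt_depth=alt_depth,
                         total_depth=round(alt_depth / vaf), vaf=vaf)
        assert is_high_confidence(call, CFG) is expected

    def test_literal_ct_reading_available(self):
        literal = FilterConfig(ct_strand_symmetric=False)
        call = make_call(ref="G", alt="A", alt_depth=9, total_depth=200,
                         vaf=0.045)
        assert is_high_confidence(call, literal)  # treated as "other"
        assert not is_high_confidence(call, CFG)

    def test_indel_input_is_an_error(self):
        with pytest.raises(ValueError):
            is_high_confidence(make_call(ref="C", alt="CT", vaf=0.2), CFG)


class TestReplicateConsensus:
    def test_low_confidence_kept_when_twin_is_high_confidence(self):
        rep1 = make_call(alt_depth=6, total_depth=200, vaf=0.03, rep="r1")
        rep2 = make_call(alt_depth=24, total_depth=200, vaf=0.12, rep="r2")
        decisions = apply_replicate_consensus({"r1": [rep1], "r2": [rep2]}, CFG)
        assert decisions == []

    def test_discarded_when_no_replicate_is_high_confidence(self):
        rep1 = make_call(alt_depth=6, total_depth=200, vaf=0.03, rep="r1")
        rep2 = make_call(alt_depth=7, total_depth=200, vaf=0.035, rep="r2")
        decisions = apply_replicate_consensus({"r1": [rep1], "r2": [rep2]}, CFG)
        assert {(d.replicate_id, d.rule) for d in decisions} == {
            ("r1", "low_confidence"), ("r2", "low_confidence")}

    def test_single_replicate_keeps_only_high_confidence(self):
        hc = make_call(pos=100, alt_depth=30, total_depth=200, vaf=0.15)
        lc = make_call(pos=200, alt_depth=6, total_depth=200, vaf=0.03)
        decisions = apply_replicate_consensus({"r1": [hc, lc]}, CFG)
        assert [d.variant.pos for d in decisions] == [200]


class TestSimpleFilters:
    def test_indel_vaf_boundary(self):
        drop = make_call(ref="C", alt="CT", vaf=0.09)
        keep = make_call(pos=101, ref="C", alt="CT", vaf=0.10)
        high = make_call(pos=102, ref="C", alt="CT", vaf=0.5)
        decisions = filter_indels([drop, keep, high], CFG)
        assert [d.variant.pos for d in decisions] == [100]

    def test_population_threshold_arithmetic(self):
        common = make_call(pos=100)
        rare = make_call(pos=200)
        absent = make_call(pos=300)
        table = PopulationFrequencyTable({
            common.variant: 8 / 722,   # 0.0111 >= 1% -> removed
            rare.variant: 7 / 722,     # 0.0097 < 1% -> kept
        })
        decisions = population_filter([common, rare, absent], table, CFG)
        assert [d.variant.pos for d in decisions] == [100]
        assert decisions[0].rule == FILTER_POPULATION


def _mini_cohort(n_samples=21, secondary_vafs=(0.02, 0.03, 0.01),
                 key_pos=500):
    """One key called by the primary caller in sample S1 and present in
    the raw secondary calls of a few other samples."""
    samples = [SampleMeta(f"S{i}", f"P{i}", "canine", "skin", "canine_skin",
                          replicate_ids=["r1"]) for i in range(1, n_samples + 1)]
    calls = {}
    primary = make_call(pos=key_pos, sample="S1", alt_depth=40,
                        total_depth=200, vaf=0.2)
    calls[("S1", "r1", CallerRole.PRIMARY_SNV)] = [primary]
    for i, vaf in enumerate(secondary_vafs, start=2):
        calls[(f"S{i}", "r1", CallerRole.SECONDARY_RAW)] = [
            make_call(pos=key_pos, sample=f"S{i}", alt_depth=round(vaf * 200),
                      total_depth=200, vaf=round(vaf * 200) / 200,
                      role=CallerRole.SECONDARY_RAW)]
    return CohortCalls(samples=samples, calls=calls), primary.variant


class TestRecurrentArtifactFilter:
    def test_flagged_when_fraction_and_homogeneity_hold(self):
        cohort, key = _mini_cohort()  # 3 of 20 primary-negative, all < 0.05
        decisions = recurrent_artifact_filter(cohort, {"S1": {key}}, CFG)
        assert [(d.sample_id, d.rule) for d in decisions] == [
            ("S1", FILTER_RECURRENT)]

    def test_below_fraction_kept(self):
        cohort, key = _mini_cohort(secondary_vafs=(0.02,))  # 1 of 20
        assert recurrent_artifact_filter(cohort, {"S1": {key}}, CFG) == []

    def test_mixed_vaf_strata_kept_under_homogeneity_reading(self):
        cohort, key = _mini_cohort(secondary_vafs=(0.02, 0.30, 0.01))
        assert recurrent_artifact_filter(cohort, {"S1": {key}}, CFG) == []

    def test_strata_reading_flags_when_one_stratum_suffices(self):
        cfg = FilterConfig(recurrent_homogeneity_required=False)
        cohort, key = _mini_cohort(
            secondary_vafs=(0.02, 0.30, 0.01, 0.015))  # low stratum: 3/20
        decisions = recurrent_artifact_filter(cohort, {"S1": {key}}, cfg)
        assert len(decisions) == 1

    def test_tiny_cohort_disables_filter(self, caplog):
        cohort, key = _mini_cohort(n_samples=1, secondary_vafs=())
        with caplog.at_level("WARNING"):
            assert recurrent_artifact_filter(cohort, {"S1": {key}}, CFG) == []
        assert "disabled" in caplog.text


class TestCascadeProperties:
    def test_per_call_filters_commute(self, small_cohort, reference):
        """Population, oxidation and indel filters depend only on the
        single call plus static tables, so the failed-call set is the
        union of the three rule outputs in any order."""
        from ffpesoma.io import trinucleotide_context

        cohort = small_cohort.cohort
        table = small_cohort.population
        meta = cohort.samples[0]
        calls = cohort.candidates(meta.sample_id, "r1")

        def run(order):
            removed = set()
            for stage in order:
                if stage == "population":
                    removed |= {d.variant for d in
                                population_filter(calls, table, CFG)}
                elif stage == "indel":
                    removed |= {d.variant for d in filter_indels(calls, CFG)}
                else:
                    for c in calls:
                        if not c.variant.is_snv:
                            continue
                        ctx = trinucleotide_context(
                            reference, c.variant.chrom, c.variant.pos)
                        if classify_oxidation(c, ctx, CFG):
                            removed.add(c.variant)
            return removed

        import itertools
        results = {frozenset(run(order))
                   for order in itertools.permutations(
                       ["population", "oxidation", "indel"])}
        assert len(results) == 1

    def test_raising_read_threshold_only_shrinks_pass_set(
            self, small_cohort, reference):
        loose = run_filter_cascade(small_cohort.cohort, reference,
                                   small_cohort.population, FilterConfig())
        strict = run_filter_cascade(
            small_cohort.cohort, reference, small_cohort.population,
            FilterConfig(ct_min_alt_reads=25))
        for sid in loose.final:
            assert strict.final_keys(sid) <= loose.final_keys(sid)

    def test_rescue_never_resurrects_key_level_failures(self, cascade):
        failed_keys = {
            (d.sample_id, d.variant)
            for d in cascade.decisions
            if d.rule in (FILTER_OXIDATION, FILTER_POPULATION,
                          FILTER_RECURRENT)}
        rescued = [(d.sample_id, d.variant) for d in cascade.decisions
                   if d.rule == FILTER_RESCUED]
        assert rescued  # the generator plants rescue sites
        assert not (set(rescued) & failed_keys)

    def test_report_accounts_for_every_candidate(self, cascade,
                                                 default_cohort):
        cohort = default_cohort.cohort
        for meta in cohort.samples:
            n_candidates = sum(
                len(cohort.candidates(meta.sample_id, rep))
                for rep in meta.replicate_ids)
            assert cascade.report.input_count(meta.sample_id) == n_candidates

    def test_planted_oxidation_artifacts_flagged_when_in_vaf_window(
            self, cascade, default_cohort):
        """Every planted OxoG artifact whose observed VAF is within the
        <= 0.10 window carries the oxidation verdict; escapes require
        sequencing noise to push the realized VAF past the window."""
        truth = default_cohort.truth_by_sample()
        cohort = default_cohort.cohort
        flagged = {(d.sample_id, d.replicate_id, d.variant)
                   for d in cascade.decisions if d.rule == FILTER_OXIDATION}
        n_checked = 0
        for meta in cohort.samples:
            sid = meta.sample_id
            oxo = {k for k, r in truth[sid].items()
                   if r.truth_class == "oxidation_artifact"}
            for rep in meta.replicate_ids:
                for call in cohort.candidates(sid, rep):
                    if call.variant in oxo and call.vaf <= 0.10:
                        assert (sid, rep, call.variant) in flagged
                        n_checked += 1
            # final sets may carry only the rare noise-escaped artifacts
            escaped = oxo & cascade.final_keys(sid)
            assert len(escaped) <= 0.02 * max(1, len(oxo))
        assert n_checked > 1000

    def test_no_population_variant_survives(self, cascade, default_cohort):
        table = default_cohort.population
        for sid in cascade.final:
            for key in cascade.final_keys(sid):
                assert table.af(key) < CFG.population_af_max
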