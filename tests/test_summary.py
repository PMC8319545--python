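import pandas as pd
import pytest

from ffpesoma.model import GenomicVariant, SampleMeta
from ffpesoma.summary import (
    CaseCallSet,
    collapse_cases,
    cross_species_overlap,
    gene_recurrence,
    germline_risk_screen,
    multi_hit_cases,
    normalize_symbol,
    render_oncoprint,
)
from helpers import make_call


def meta(sample_id, patient_id, tissue="cardiac", cohort="canine_visceral",
         species="canine"):
    return SampleMeta(sample_id, patient_id, species, tissue, cohort,
                      replicate_ids=["r1"])


def call_at(pos, gene, consequence="missense", sample="S", alt="T", ref="C"):
    return make_call(pos=pos, ref=ref, alt=alt, sample=sample, gene=gene,
                     consequence=consequence,
                     protein_altering=consequence in
                     ("missense", "nonsense", "frameshift", "inframe"))


class TestCollapse:
    def test_heart_only_mutation_counts_for_the_case(self):
        manifest = [meta("P1_cardiac", "P1"),
                    meta("P1_splenic", "P1", "splenic")]
        heart = call_at(100, "TP53", sample="P1_cardiac")
        final = {"P1_cardiac": {heart.variant: heart}, "P1_splenic": {}}
        cases = collapse_cases(manifest, final)
        assert len(cases) == 1
        assert cases[0].genes() == {"TP53"}

    def test_same_key_in_both_lesions_is_one_entry(self):
        manifest = [meta("P1_cardiac", "P1"),
                    meta("P1_splenic", "P1", "splenic")]
        a = call_at(100, "TP53", "synonymous", sample="P1_cardiac")
        b = call_at(100, "TP53", "nonsense", sample="P1_splenic")
        cases = collapse_cases(manifest, {"P1_cardiac": {a.variant: a},
                                          "P1_splenic": {b.variant: b}})
        assert len(cases[0].calls) == 1
        # the most severe consequence wins the annotation conflict
        assert next(iter(cases[0].calls.values())).consequence == "nonsense"

    def test_collapsing_is_idempotent(self):
        manifest = [meta("P1_cardiac", "P1"),
                    meta("P1_splenic", "P1", "splenic")]
        a = call_at(100, "TP53", sample="P1_cardiac")
        b = call_at(200, "PTEN", sample="P1_splenic")
        once = collapse_cases(manifest, {"P1_cardiac": {a.variant: a},
                                         "P1_splenic": {b.variant: b}})
        again = collapse_cases([meta("P1_x", "P1")],
                               {"P1_x": dict(once[0].calls)})
        assert again[0].calls == once[0].calls

    def test_patient_without_samples_errors(self):
        manifest = [meta("P1_cardiac", "P1"), meta("P2_cardiac", "P2")]
        with pytest.raises(ValueError, match="zero samples"):
            collapse_cases(manifest, {"P1_cardiac": {}})


class TestRecurrence:
    def _cases(self):
        cases = []
        for i, genes in enumerate([("TP53", "PIK3CA"), ("TP53",), ()]):
            case = CaseCallSet(patient_id=f"P{i}", cohort="canine_visceral")
            for j, gene in enumerate(genes):
                call = call_at(100 + 10 * i + j, gene)
                case.calls[call.variant] = call
            cases.append(case)
        return cases

    def test_counting(self):
        table = gene_recurrence(self._cases())
        tp53 = table[table["gene"] == "TP53"].iloc[0]
        assert (tp53.n_cases_mutated, tp53.n_cases_total) == (2, 3)
        assert tp53.fraction == pytest.approx(2 / 3)

    def test_synonymous_only_case_not_counted(self):
        case = CaseCallSet(patient_id="P9", cohort="canine_skin")
        call = call_at(500, "TP53", "synonymous")
        case.calls[call.variant] = call
        table = gene_recurrence([case])
        assert table.empty
        permissive = gene_recurrence([case], protein_altering_only=False)
        assert permissive.iloc[0].n_cases_mutated == 1

    def test_uv_exclusion_shrinks_both_counts(self):
        cases = self._cases()
        table = gene_recurrence(cases, exclude_uv=True,
                                uv_flags={"P1": True})
        tp53 = table[table["gene"] == "TP53"].iloc[0]
        assert (tp53.n_cases_mutated, tp53.n_cases_total) == (1, 2)

    def test_matches_brute_force_scan(self, cascade, default_cohort):
        cases = collapse_cases(default_cohort.cohort.samples, cascade.final)
        table = gene_recurrence(cases)
        for row in table.sample(25, random_state=0).itertuples(index=False):
            expected = sum(
                1 for case in cases
                if case.cohort == row.cohort and any(
                    normalize_symbol(c.gene) == row.gene
                    and c.is_protein_altering
                    for c in case.calls.values()))
            assert row.n_cases_mutated == expected


class TestMultiHit:
    def test_distinct_key_requirement(self):
        case = CaseCallSet(patient_id="P1", cohort="canine_visceral")
        a = call_at(100, "TP53")
        b = call_at(200, "TP53", "nonsense")
        case.calls[a.variant] = a
        case.calls[b.variant] = b
        single = CaseCallSet(patient_id="P2", cohort="canine_visceral")
        single.calls[a.variant] = a
        assert multi_hit_cases([case, single], "TP53") == 1

    def test_matches_brute_force_tally(self, cascade, default_cohort):
        cases = collapse_cases(default_cohort.cohort.samples, cascade.final)
        for gene in ("TP53", "PIK3CA", "ATRX"):
            expected = 0
            for case in cases:
                keys = [k for k, c in case.calls.items()
                        if normalize_symbol(c.gene) == gene
                        and c.is_protein_altering]
                if len(set(keys)) >= 2:
                    expected += 1
            assert multi_hit_cases(cases, gene) == expected


class TestCrossSpecies:
    def _recurrence(self):
        return pd.DataFrame([
            ("canine_visceral", "TP53", 14, 15, 14 / 15),
            ("canine_skin", "PRKDC", 2, 13, 2 / 13),
            ("feline_skin", "TP53", 6, 13, 6 / 13),
            ("feline_skin", "NOTCH1", 2, 13, 2 / 13),
        ], columns=["cohort", "gene", "n_cases_mutated", "n_cases_total",
                    "fraction"])

    def test_two_species_rule(self):
        human = pd.DataFrame({"gene": ["TP53", "NOTCH1", "KDR"],
                              "fraction": [0.21, 0.08, 0.1]})
        table = cross_species_overlap(self._recurrence(), human)
        genes = set(table["gene"])
        assert "TP53" in genes       # canine + feline + human
        assert "NOTCH1" in genes     # feline + human
        assert "PRKDC" not in genes  # canine only
        assert "KDR" not in genes    # human only
        tp53 = table[table["gene"] == "TP53"].iloc[0]
        assert tp53.canine_fraction == pytest.approx(14 / 15)
        assert tp53.n_species == 3

    def test_matches_set_intersection_oracle(self):
        human = pd.DataFrame({"gene": ["TP53", "NOTCH1"],
                              "fraction": [0.21, 0.08]})
        rec = self._recurrence()
        table = cross_species_overlap(rec, human)
        species_sets = {
            "canine": {g for c, g in zip(rec["cohort"], rec["gene"])
                       if c.startswith("canine")},
            "feline": {g for c, g in zip(rec["cohort"], rec["gene"])
                       if c.startswith("feline")},
            "human": set(human["gene"]),
        }
        expected = {g for g in set().union(*species_sets.values())
                    if sum(g in s for s in species_sets.values()) >= 2}
        assert set(table["gene"]) == expected

    def test_empty_human_list_errors(self):
        with pytest.raises(ValueError):
            cross_species_overlap(self._recurrence(),
                                  pd.DataFrame(columns=["gene", "fraction"]))


class TestGermlineScreen:
    def test_gene_and_consequence_gates(self):
        calls = {
            "P1": [call_at(100, "IDH1", "missense"),
                   call_at(200, "TP53", "synonymous"),
                   call_at(300, "BRAF", "missense")],
        }
        table = germline_risk_screen(calls)
        assert table["gene"].tolist() == ["IDH1"]
        assert bool(table["reference_error_caution"].iloc[0]) is True
        with pytest.raises(ValueError):
            germline_risk_screen(calls, risk_genes=())

    def test_finds_planted_risk_variants(self, default_cohort):
        table = germline_risk_screen(default_cohort.germline_calls)
        assert len(table) > 0
        from ffpesoma.summary import RISK_GENES
        assert set(table["gene"]) <= set(RISK_GENES)


class TestOncoprint:
    def test_empty_and_single_gene(self, tmp_path):
        empty = render_oncoprint([], out_tsv=tmp_path / "empty.tsv")
        assert empty.empty
        assert (tmp_path / "empty.tsv").exists()
        case = CaseCallSet(patient_id="P1", cohort="canine_skin")
        call = call_at(100, "TP53")
        case.calls[call.variant] = call
        matrix = render_oncoprint([case])
        assert matrix.shape == (1, 1)
        assert matrix.loc["TP53", "P1"] == "missense"

    def test_row_order_stable_and_recurrence_consistent(
            self, cascade, default_cohort, tmp_path):
        cases = collapse_cases(default_cohort.cohort.samples, cascade.final)
        a = render_oncoprint(cases)
        b = render_oncoprint(cases, out_plot=tmp_path / "oncoprint.png")
        assert a.equals(b)
        # self-consistency: recurrence recomputed from the matrix
        table = gene_recurrence(cases)
        totals = table.groupby("gene")["n_cases_mutated"].sum()
        for gene in a.index:
            assert (a.loc[gene] != "").sum() == totals[gene]
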