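"""Somatic-variant filtering cascade for duplicate-core FFPE panel data.

FFPE-derived DNA carries two dominant artifact modes: cytosine
deamination (low-VAF C>T) and oxidative damage to guanine ("OxoG",
low-VAF C>A biased toward CCN/TCN contexts). The cascade removes them
using, in order:

1. population filter — germline leakage at >= 1% panel allele frequency;
2. oxidation-context filter — C>A (or G>T on the reverse strand) at
   VAF <= 0.10 in CCN/TCN (NGG/NGA) context;
3. high-confidence thresholds with replicate consensus — a call below the
   read-support/VAF bar survives only if the same mutation is
   high-confidence in the other extraction replicate of the same core pair;
4. indel VAF filter;
5. recurrent-artifact filter — a key seen by the raw secondary caller in
   >= 10% of samples where the primary caller was silent, with homogeneous
   VAFs, is a systematic artifact;
6. cross-caller rescue — a high-confidence call present in one replicate
   and absent from the other's primary output is restored there when the
   raw secondary caller observed it.

The final per-sample call set is the union of surviving replicate calls
collapsed by variant key.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from pyfaidx import Fasta

from .io import trinucleotide_context
from .model import (
    FILTER_INDEL_LOW_VAF,
    FILTER_LOW_CONFIDENCE,
    FILTER_OXIDATION,
    FILTER_PASS,
    FILTER_POPULATION,
    FILTER_RECURRENT,
    FILTER_RESCUED,
    CallerRole,
    FilterConfig,
    GenomicVariant,
    PopulationFrequencyTable,
    SampleMeta,
    VariantCall,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortCalls",
    "FilterDecision",
    "FilterReport",
    "CascadeResult",
    "classify_oxidation",
    "is_high_confidence",
    "apply_replicate_consensus",
    "filter_indels",
    "population_filter",
    "recurrent_artifact_filter",
    "rescue_replicate_false_negative",
    "run_filter_cascade",
]

CASCADE_ORDER = (
    FILTER_POPULATION,
    FILTER_OXIDATION,
    FILTER_LOW_CONFIDENCE,
    FILTER_INDEL_LOW_VAF,
    FILTER_RECURRENT,
    FILTER_RESCUED,
)


@dataclass
class CohortCalls:
    """All call sets for one cohort, keyed by (sample, replicate, role)."""

    samples: list[SampleMeta]
    calls: dict[tuple[str, str, CallerRole], list[VariantCall]]

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def get(self, sample_id: str, replicate_id: str,
            role: CallerRole) -> list[VariantCall]:
        return self.calls.get((sample_id, replicate_id, role), [])

    def candidates(self, sample_id: str, replicate_id: str) -> list[VariantCall]:
        """Primary-caller candidates entering the cascade (SNVs + indels)."""
        return (self.get(sample_id, replicate_id, CallerRole.PRIMARY_SNV)
                + self.get(sample_id, replicate_id, CallerRole.INDEL))

    def secondary_keys(self, sample_id: str) -> dict[GenomicVariant, list[float]]:
        """Raw secondary-caller VAFs per key, pooled over replicates."""
        meta = next(s for s in self.samples if s.sample_id == sample_id)
        out: dict[GenomicVariant, list[float]] = defaultdict(list)
        for rep in meta.replicate_ids:
            for call in self.get(sample_id, rep, CallerRole.SECONDARY_RAW):
                out[call.variant].append(call.vaf)
        return dict(out)


@dataclass(frozen=True)
class FilterDecision:
    """Terminal verdict for one candidate call (or a rescued absence)."""

    variant: GenomicVariant
    sample_id: str
    replicate_id: str
    verdict: str  # "pass" | "fail" | "rescued"
    rule: str  # FILTER vocabulary string ("PASS" for passing calls)
    detail: str = ""


@dataclass
class FilterReport:
    """Per-sample accounting: every input candidate gets exactly one verdict."""

    cascade_order: tuple[str, ...] = CASCADE_ORDER
    per_sample: dict[str, Counter] = field(default_factory=dict)

    def tally(self, decision: FilterDecision) -> None:
        counter = self.per_sample.setdefault(decision.sample_id, Counter())
        counter[decision.rule] += 1

    def input_count(self, sample_id: str) -> int:
        counter = self.per_sample.get(sample_id, Counter())
        return sum(v for rule, v in counter.items() if rule != FILTER_RESCUED)


@dataclass
class CascadeResult:
    final: dict[str, dict[GenomicVariant, VariantCall]]
    decisions: list[FilterDecision]
    report: FilterReport

    def final_keys(self, sample_id: str) -> set[GenomicVariant]:
        return set(self.final.get(sample_id, {}))


def classify_oxidation(call: VariantCall, context: str | None,
                       config: FilterConfig) -> bool | None:
    """OxoG artifact test for a single SNV.

    True iff the call is C>A at VAF <= the cutoff in CCN/TCN context, or
    its reverse-strand mirror G>T in NGG/NGA context. Returns ``None``
    (not applicable) for non-SNVs or when the context is unavailable.
    """
    v = call.variant
    if not v.is_snv:
        return None
    if (v.ref, v.alt) not in (("C", "A"), ("G", "T")):
        return False
    if context is None:
        return None
    if len(context) != 3 or context[1] != v.ref:
        raise ValueError(
            f"context {context!r} does not center on ref base {v.ref}")
    if call.vaf > config.oxidation_vaf_max:
        return False
    if v.ref == "C":
        return context[0] in "CT"  # CCN or TCN
    return context[2] in "GA"  # NGG or NGA


def is_high_confidence(call: VariantCall, config: FilterConfig) -> bool:
    """High-confidence test for a primary-caller substitution.

    C>T calls (and G>A when the strand-symmetric reading is on) face the
    stricter deamination-aware bar: >= ``ct_min_alt_reads`` supporting
    reads AND VAF strictly above ``ct_min_vaf_exclusive``. All other
    substitutions need >= ``other_min_alt_reads`` reads and VAF >=
    ``other_min_vaf_inclusive`` (inclusive). Multi-nucleotide substitutions
    use the "other" thresholds. Indels are out of scope here.
    """
    v = call.variant
    if v.is_indel:
        raise ValueError("indels have their own VAF rule; not a substitution")
    ct_like = (v.ref, v.alt) == ("C", "T") or (
        config.ct_strand_symmetric and (v.ref, v.alt) == ("G", "A"))
    if ct_like:
        return (call.alt_depth >= config.ct_min_alt_reads
                and call.vaf > config.ct_min_vaf_exclusive)
    return (call.alt_depth >= config.other_min_alt_reads
            and call.vaf >= config.other_min_vaf_inclusive)


def filter_indels(calls: list[VariantCall],
                  config: FilterConfig) -> list[FilterDecision]:
    """Discard indels below the VAF floor (strict <, as published)."""
    decisions = []
    for call in calls:
        if not call.variant.is_indel:
            continue
        if call.vaf < config.indel_min_vaf:
            decisions.append(FilterDecision(
                call.variant, call.sample_id, call.replicate_id,
                "fail", FILTER_INDEL_LOW_VAF, f"vaf={call.vaf:.4f}"))
    return decisions


def population_filter(calls: list[VariantCall],
                      table: PopulationFrequencyTable,
                      config: FilterConfig) -> list[FilterDecision]:
    """Remove calls whose key reaches the population AF cutoff (>= 1%)."""
    decisions = []
    for call in calls:
        af = table.af(call.variant)
        if af >= config.population_af_max:
            decisions.append(FilterDecision(
                call.variant, call.sample_id, call.replicate_id,
                "fail", FILTER_POPULATION, f"af={af:.4f}"))
    return decisions


def apply_replicate_consensus(
        calls_by_replicate: dict[str, list[VariantCall]],
        config: FilterConfig) -> list[FilterDecision]:
    """High-confidence thresholds with cross-replicate consensus.

    A substitution that fails the high-confidence bar in its own
    replicate survives iff the same variant key is high-confidence in
    another replicate of the same sample; in a single-replicate sample
    only high-confidence calls survive.
    """
    hc_keys_by_rep = {
        rep: {c.variant for c in calls if not c.variant.is_indel
              and is_high_confidence(c, config)}
        for rep, calls in calls_by_replicate.items()
    }
    decisions = []
    for rep, calls in calls_by_replicate.items():
        others: set[GenomicVariant] = set()
        for other_rep, keys in hc_keys_by_rep.items():
            if other_rep != rep:
                others |= keys
        for call in calls:
            if call.variant.is_indel:
                continue
            if call.variant in hc_keys_by_rep[rep] or call.variant in others:
                continue
            decisions.append(FilterDecision(
                call.variant, call.sample_id, rep, "fail",
                FILTER_LOW_CONFIDENCE,
                f"alt_depth={call.alt_depth} vaf={call.vaf:.4f}"))
    return decisions


def _recurrent_strata(vafs: list[float], split: float) -> str:
    if all(v < split for v in vafs):
        return "low"
    if all(v >= split for v in vafs):
        return "high"
    return "mixed"


def recurrent_artifact_filter(
        cohort: CohortCalls,
        candidate_keys_by_sample: dict[str, set[GenomicVariant]],
        config: FilterConfig) -> list[FilterDecision]:
    """Cross-cohort systematic-artifact filter against raw secondary calls.

    For each primary-called key, consider the samples where the primary
    caller made *no* call at that key; if the raw secondary caller sees
    the key in at least ``recurrent_sample_fraction`` of them, and those
    VAFs are homogeneous (all below or all at/above the VAF split), the
    key is a recurrent artifact everywhere the primary called it.
    """
    sample_ids = cohort.sample_ids()
    if len(sample_ids) < 2:
        logger.warning("recurrent-artifact filter disabled: cohort has "
                       "%d sample(s)", len(sample_ids))
        return []

    # Samples with any primary/indel call at each key (raw caller output).
    primary_positive: dict[GenomicVariant, set[str]] = defaultdict(set)
    for sample in cohort.samples:
        for rep in sample.replicate_ids:
            for call in cohort.candidates(sample.sample_id, rep):
                primary_positive[call.variant].add(sample.sample_id)
    secondary = {sid: cohort.secondary_keys(sid) for sid in sample_ids}

    flagged: dict[GenomicVariant, str] = {}
    all_keys = set().union(*candidate_keys_by_sample.values()) \
        if candidate_keys_by_sample else set()
    for key in all_keys:
        negatives = [sid for sid in sample_ids
                     if sid not in primary_positive[key]]
        supported = {sid: secondary[sid][key] for sid in negatives
                     if key in secondary[sid]}
        denom = (len(negatives) if config.recurrent_denominator ==
                 "primary_negative" else len(sample_ids))
        if denom == 0 or not supported:
            continue
        threshold = config.recurrent_sample_fraction * denom
        split = config.recurrent_vaf_split
        if config.recurrent_homogeneity_required:
            pooled = [v for vafs in supported.values() for v in vafs]
            stratum = _recurrent_strata(pooled, split)
            hit = len(supported) >= threshold - 1e-9 and stratum != "mixed"
            detail = f"{len(supported)}/{denom} secondary-positive, {stratum} VAFs"
        else:
            # Alternative reading: each VAF stratum is independently
            # sufficient; a sample counts in a stratum only if all its
            # secondary VAFs fall on one side of the split.
            strata = Counter(_recurrent_strata(v, split)
                             for v in supported.values())
            hit = (strata["low"] >= threshold - 1e-9
                   or strata["high"] >= threshold - 1e-9)
            detail = (f"low={strata['low']} high={strata['high']} of {denom}")
        if hit:
            flagged[key] = detail

    decisions = []
    for sample_id, keys in candidate_keys_by_sample.items():
        for key in keys & set(flagged):
            decisions.append(FilterDecision(
                key, sample_id, "*", "fail", FILTER_RECURRENT, flagged[key]))
    return decisions


def rescue_replicate_false_negative(
        sample: SampleMeta,
        surviving_by_rep: dict[str, dict[GenomicVariant, VariantCall]],
        cohort: CohortCalls,
        config: FilterConfig) -> list[FilterDecision]:
    """Cross-caller rescue of replicate-level false negatives.

    A key that survived as high-confidence in replicate A but was never
    called by the primary caller in replicate B is restored in B when
    the raw secondary caller observed it there.
    """
    decisions = []
    reps = sample.replicate_ids
    primary_keys = {rep: {c.variant for c in
                          cohort.candidates(sample.sample_id, rep)}
                    for rep in reps}
    secondary_keys = {
        rep: {c.variant for c in
              cohort.get(sample.sample_id, rep, CallerRole.SECONDARY_RAW)}
        for rep in reps}
    for rep_a in reps:
        for key, call in surviving_by_rep.get(rep_a, {}).items():
            if key.is_indel or not is_high_confidence(call, config):
                continue
            for rep_b in reps:
                if rep_b == rep_a or key in primary_keys[rep_b]:
                    continue
                if key in secondary_keys[rep_b]:
                    decisions.append(FilterDecision(
                        key, sample.sample_id, rep_b, "rescued",
                        FILTER_RESCUED, f"high-confidence in {rep_a}"))
    return decisions


def run_filter_cascade(cohort: CohortCalls, reference: Fasta,
                       population: PopulationFrequencyTable,
                       config: FilterConfig | None = None) -> CascadeResult:
    """Apply the full cascade and collapse surviving calls per sample.

    Order: population -> oxidation -> high-confidence/replicate consensus
    -> indel VAF -> recurrent artifact -> rescue. Each candidate call
    receives exactly one terminal verdict; the final per-sample set is
    the key-collapsed union over replicates of passing and rescued calls.
    """
    config = config or FilterConfig()
    decisions: list[FilterDecision] = []
    report = FilterReport()

    failed: dict[tuple[str, str, GenomicVariant], FilterDecision] = {}

    def record_fail(decision: FilterDecision) -> None:
        ident = (decision.sample_id, decision.replicate_id, decision.variant)
        if ident not in failed:
            failed[ident] = decision

    # Stages 1-2 are per-call and key/context-static; stage 3 needs the
    # sample's replicates jointly; stage 4 is per-call.
    per_rep_survivors: dict[str, dict[str, dict[GenomicVariant, VariantCall]]] = {}
    for sample in cohort.samples:
        calls_by_rep = {rep: cohort.candidates(sample.sample_id, rep)
                        for rep in sample.replicate_ids}
        all_calls = [c for calls in calls_by_rep.values() for c in calls]
        for decision in population_filter(all_calls, population, config):
            record_fail(decision)
        for call in all_calls:
            if not call.variant.is_snv:
                continue
            context = trinucleotide_context(
                reference, call.variant.chrom, call.variant.pos)
            if classify_oxidation(call, context, config):
                record_fail(FilterDecision(
                    call.variant, call.sample_id, call.replicate_id,
                    "fail", FILTER_OXIDATION,
                    f"vaf={call.vaf:.4f} context={context}"))
        # Replicate consensus is evaluated on calls still alive after the
        # key-level stages (a population/oxidation-failed call cannot vouch
        # for its twin).
        alive_by_rep = {
            rep: [c for c in calls
                  if (sample.sample_id, rep, c.variant) not in failed]
            for rep, calls in calls_by_rep.items()}
        for decision in apply_replicate_consensus(alive_by_rep, config):
            record_fail(decision)
        for decision in filter_indels(all_calls, config):
            record_fail(decision)
        per_rep_survivors[sample.sample_id] = {
            rep: {c.variant: c for c in calls
                  if (sample.sample_id, rep, c.variant) not in failed}
            for rep, calls in calls_by_rep.items()}

    # Stage 5: cohort-wide recurrent-artifact filter on surviving keys.
    candidate_keys = {
        sid: set().union(*(set(d) for d in survivors.values())) if survivors else set()
        for sid, survivors in per_rep_survivors.items()}
    for decision in recurrent_artifact_filter(cohort, candidate_keys, config):
        # Key-level failure: mark in every replicate still carrying it.
        survivors = per_rep_survivors[decision.sample_id]
        for rep, keyed in survivors.items():
            if decision.variant in keyed:
                record_fail(FilterDecision(
                    decision.variant, decision.sample_id, rep, "fail",
                    FILTER_RECURRENT, decision.detail))
                del keyed[decision.variant]

    # Stage 6: rescue; never resurrects oxidation/population/recurrent
    # failures because only keys surviving in the vouching replicate are
    # eligible, and those rules are key-level within a sample.
    rescued: list[FilterDecision] = []
    for sample in cohort.samples:
        if len(sample.replicate_ids) < 2:
            continue
        rescued.extend(rescue_replicate_false_negative(
            sample, per_rep_survivors[sample.sample_id], cohort, config))

    # Assemble decisions: one terminal verdict per candidate call.
    final: dict[str, dict[GenomicVariant, VariantCall]] = {}
    for sample in cohort.samples:
        survivors = per_rep_survivors[sample.sample_id]
        collapsed: dict[GenomicVariant, VariantCall] = {}
        for rep in sample.replicate_ids:
            for call in cohort.candidates(sample.sample_id, rep):
                ident = (sample.sample_id, rep, call.variant)
                if ident in failed:
                    decision = failed[ident]
                else:
                    decision = FilterDecision(
                        call.variant, sample.sample_id, rep, "pass",
                        FILTER_PASS, f"vaf={call.vaf:.4f}")
                    existing = collapsed.get(call.variant)
                    if existing is None or call.total_depth > existing.total_depth:
                        collapsed[call.variant] = call
                decisions.append(decision)
                report.tally(decision)
        final[sample.sample_id] = collapsed
    for decision in rescued:
        decisions.append(decision)
        report.tally(decision)

    return CascadeResult(final=final, decisions=decisions, report=report)
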