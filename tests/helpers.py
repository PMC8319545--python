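"""Shared test helpers: call construction and independent rule oracles."""

from ffpesoma.model import CallerRole, GenomicVariant, VariantCall


def make_call(chrom="chr1", pos=100, ref="C", alt="T", sample="S1",
              rep="r1", role=CallerRole.PRIMARY_SNV, alt_depth=None,
              total_depth=200, vaf=None, gene="", consequence="",
              protein_altering=False):
    """Build a consistent VariantCall from whichever of vaf/alt_depth is given."""
    if alt_depth is None and vaf is None:
        vaf = 0.25
    if alt_depth is None:
        alt_depth = round(vaf * total_depth)
    if vaf is None:
        vaf = alt_depth / total_depth if total_depth else 0.0
    if len(ref) != len(alt):
        role = CallerRole.INDEL
    return VariantCall(
        variant=GenomicVariant(chrom, pos, ref, alt), sample_id=sample,
        replicate_id=rep, caller_role=role, alt_depth=alt_depth,
        total_depth=total_depth, vaf=vaf, gene=gene, consequence=consequence,
        is_protein_altering=protein_altering)


def oracle_final_sets(cohort, reference, population, config):
    """Independent single-pass evaluation of the printed filtering rules.

    Deliberately written as plain nested loops over every candidate,
    sharing no logic with the cascade implementation; returns
    (final key sets per sample, rescued (sample, key) pairs).
    """
    from ffpesoma.io import trinucleotide_context
    from ffpesoma.model import CallerRole

    samples = cohort.samples
    sample_ids = [s.sample_id for s in samples]

    def primary_calls(sid, rep):
        return (cohort.calls.get((sid, rep, CallerRole.PRIMARY_SNV), [])
                + cohort.calls.get((sid, rep, CallerRole.INDEL), []))

    def is_hc(call):
        r, a = call.variant.ref, call.variant.alt
        ct = (r, a) == ("C", "T") or (config.ct_strand_symmetric
                                      and (r, a) == ("G", "A"))
        if ct:
            return call.alt_depth >= config.ct_min_alt_reads and \
                call.vaf > config.ct_min_vaf_exclusive
        return call.alt_depth >= config.other_min_alt_reads and \
            call.vaf >= config.other_min_vaf_inclusive

    def is_oxo(call):
        v = call.variant
        if len(v.ref) != 1 or len(v.alt) != 1:
            return False
        ctx = trinucleotide_context(reference, v.chrom, v.pos)
        if ctx is None or call.vaf > config.oxidation_vaf_max:
            return False
        if (v.ref, v.alt) == ("C", "A"):
            return ctx[0] in "CT"
        if (v.ref, v.alt) == ("G", "T"):
            return ctx[2] in "GA"
        return False

    # pass/fail per (sample, rep, key) through stages 1-4
    survived = {}
    for meta in samples:
        sid = meta.sample_id
        for rep in meta.replicate_ids:
            for call in primary_calls(sid, rep):
                v = call.variant
                ok = True
                if population.af(v) >= config.population_af_max:
                    ok = False
                elif is_oxo(call):
                    ok = False
                elif v.is_indel:
                    ok = call.vaf >= config.indel_min_vaf
                elif not is_hc(call):
                    # consensus: HC in another replicate, itself alive
                    # through the key-level stages
                    ok = False
                    for rep2 in meta.replicate_ids:
                        if rep2 == rep:
                            continue
                        for other in primary_calls(sid, rep2):
                            if other.variant != v or other.variant.is_indel:
                                continue
                            if population.af(v) >= config.population_af_max:
                                continue
                            if is_oxo(other):
                                continue
                            if is_hc(other):
                                ok = True
                survived[(sid, rep, v)] = (ok, call)

    # recurrent-artifact rule over surviving keys
    def secondary_vafs(sid, key):
        meta = next(s for s in samples if s.sample_id == sid)
        vafs = []
        for rep in meta.replicate_ids:
            for c in cohort.calls.get((sid, rep, CallerRole.SECONDARY_RAW), []):
                if c.variant == key:
                    vafs.append(c.vaf)
        return vafs

    primary_positive = {}
    for meta in samples:
        for rep in meta.replicate_ids:
            for call in primary_calls(meta.sample_id, rep):
                primary_positive.setdefault(call.variant, set()).add(
                    meta.sample_id)

    surviving_keys = {(sid, v) for (sid, rep, v), (ok, _) in survived.items()
                      if ok}
    recurrent_failed = set()
    if len(sample_ids) >= 2:
        for sid, key in surviving_keys:
            negatives = [t for t in sample_ids
                         if t not in primary_positive.get(key, set())]
            pooled = []
            n_supported = 0
            for t in negatives:
                vafs = secondary_vafs(t, key)
                if vafs:
                    n_supported += 1
                    pooled.extend(vafs)
            denom = (len(negatives)
                     if config.recurrent_denominator == "primary_negative"
                     else len(sample_ids))
            if denom == 0 or n_supported == 0:
                continue
            homogeneous = (all(v < config.recurrent_vaf_split for v in pooled)
                           or all(v >= config.recurrent_vaf_split
                                  for v in pooled))
            if n_supported >= config.recurrent_sample_fraction * denom - 1e-9 \
                    and homogeneous:
                recurrent_failed.add((sid, key))

    # rescue + final sets
    final = {}
    rescued = set()
    for meta in samples:
        sid = meta.sample_id
        keys = set()
        for rep in meta.replicate_ids:
            for (s2, r2, v), (ok, call) in survived.items():
                if s2 != sid or r2 != rep or not ok:
                    continue
                if (sid, v) in recurrent_failed:
                    continue
                keys.add(v)
                if not v.is_indel and is_hc(call):
                    for rep_b in meta.replicate_ids:
                        if rep_b == rep:
                            continue
                        b_primary = {c.variant
                                     for c in primary_calls(sid, rep_b)}
                        b_secondary = {
                            c.variant for c in cohort.calls.get(
                                (sid, rep_b, CallerRole.SECONDARY_RAW), [])}
                        if v not in b_primary and v in b_secondary:
                            rescued.add((sid, rep_b, v))
        final[sid] = keys
    return final, rescued
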