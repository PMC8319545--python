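"""Readers and writers for the standard formats the pipeline touches.

VCF v4.2 read/write goes through :mod:`pysam`; reference access goes
through :mod:`pyfaidx` with ``.fai``-style random access. The VCF layer
carries depth in FORMAT ``AD``/``DP`` and annotation in INFO ``GENE`` /
``CSQ`` / ``PA``; the FILTER column carries the cascade verdict strings.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping

import pysam
from pyfaidx import Fasta

from .model import (
    FILTER_PASS,
    FILTER_VOCABULARY,
    CallerRole,
    GenomicVariant,
    VariantCall,
)

__all__ = [
    "open_reference",
    "read_vcf",
    "reverse_complement",
    "trinucleotide_context",
    "write_vcf",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def open_reference(path) -> Fasta:
    """Open a FASTA with random access (builds the .fai index if absent)."""
    return Fasta(str(path), sequence_always_upper=True)


def trinucleotide_context(reference: Fasta, chrom: str, pos: int) -> str | None:
    """Reference 3-mer centered on ``pos`` (1-based), uppercase.

    Returns ``None`` when the position sits at a contig edge, signalling
    that context-dependent rules (the oxidation filter, spectrum binning)
    are not applicable there.
    """
    if chrom not in reference:
        raise KeyError(f"contig {chrom!r} not in reference")
    contig = reference[chrom]
    if pos < 2 or pos > len(contig) - 1:
        return None
    # pyfaidx slices are 0-based half-open.
    return str(contig[pos - 2 : pos + 1]).upper()


def _field(source, key):
    """Fetch a FORMAT/INFO field, tolerating IDs absent from the header
    (pysam raises on lookups of undeclared IDs)."""
    try:
        return source.get(key)
    except (KeyError, ValueError):
        return None


def _depths_for_alt(record, alt_index: int, path) -> tuple[int, int]:
    """Extract (alt_depth, total_depth) for one ALT allele.

    FORMAT AD/DP of the first sample takes precedence; INFO AD/DP is the
    fallback. Missing depth information is an error, never a silent
    default.
    """
    n_alleles = 1 + len(record.alts or ())
    sources = ([record.samples[0]] if record.samples else []) + [record.info]
    for source in sources:
        ad = _field(source, "AD")
        dp = _field(source, "DP")
        if ad is not None and dp is not None:
            ad = tuple(ad) if isinstance(ad, (tuple, list)) else (ad,)
            if len(ad) != n_alleles:
                raise ValueError(
                    f"{path}: record {record.chrom}:{record.pos} has AD of length "
                    f"{len(ad)} for {n_alleles} alleles"
                )
            return int(ad[1 + alt_index]), int(dp)
    raise ValueError(
        f"{path}: record {record.chrom}:{record.pos} lacks AD/DP depth fields "
        "(FORMAT or INFO); depths are required"
    )


def read_vcf(path, sample_id: str, replicate_id: str,
             caller_role: CallerRole | str) -> list[VariantCall]:
    """Read one caller's VCF into :class:`VariantCall` records.

    Multi-allelic records are split into one call per ALT allele. VAF is
    always recomputed from AD/DP (a pre-computed VAF field, if present, is
    ignored). Malformed records raise with the file named.
    """
    caller_role = CallerRole(caller_role)
    calls: list[VariantCall] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for record in vcf:
            if record.alts is None:
                continue
            for alt_index, alt in enumerate(record.alts):
                alt_depth, total_depth = _depths_for_alt(record, alt_index, path)
                vaf = alt_depth / total_depth if total_depth > 0 else 0.0
                gene = _field(record.info, "GENE") or ""
                csq = _field(record.info, "CSQ") or ""
                calls.append(VariantCall(
                    variant=GenomicVariant(record.chrom, record.pos,
                                           record.ref, alt),
                    sample_id=sample_id,
                    replicate_id=replicate_id,
                    caller_role=caller_role,
                    alt_depth=alt_depth,
                    total_depth=total_depth,
                    vaf=vaf,
                    gene=str(gene),
                    consequence=str(csq),
                    is_protein_altering=bool(_field(record.info, "PA")),
                ))
    return calls


def _vcf_header(calls: Iterable[VariantCall],
                contig_lengths: Mapping[str, int] | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##source=ffpesoma')
    for name in FILTER_VOCABULARY:
        if name != FILTER_PASS:
            header.add_line(f'##FILTER=<ID={name},Description="{name}">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">')
    header.add_line('##INFO=<ID=PA,Number=0,Type=Flag,Description="Protein altering">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    if contig_lengths:
        contigs = dict(contig_lengths)
    else:
        contigs = {}
        for call in calls:
            end = call.variant.pos + len(call.variant.ref)
            contigs[call.variant.chrom] = max(contigs.get(call.variant.chrom, 0), end)
    for chrom in contigs:
        header.add_line(f'##contig=<ID={chrom},length={contigs[chrom]}>')
    return header


def write_vcf(calls: list[VariantCall], path,
              contig_lengths: Mapping[str, int] | None = None,
              filters: Mapping[GenomicVariant, str] | None = None) -> None:
    """Write calls to VCF v4.2 with the cascade verdict in FILTER.

    ``calls`` must be sorted by (chrom, pos); ``filters`` maps variant key
    to a FILTER vocabulary string (default PASS). Output is deterministic:
    rewriting a written file reproduces it byte for byte.
    """
    keys = [(c.variant.chrom, c.variant.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos) before writing")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"one VCF per sample: got {sorted(sample_ids)}")
    sample = sample_ids.pop() if sample_ids else "SAMPLE"

    header = _vcf_header(calls, contig_lengths)
    header.add_sample(sample)
    filters = filters or {}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            v = call.variant
            record = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt),
            )
            verdict = filters.get(v, FILTER_PASS)
            if verdict not in FILTER_VOCABULARY:
                raise ValueError(f"unknown FILTER string {verdict!r}")
            record.filter.add(verdict)
            if call.gene:
                record.info["GENE"] = call.gene
            if call.consequence:
                record.info["CSQ"] = call.consequence
            if call.is_protein_altering:
                record.info["PA"] = True
            ref_depth = call.total_depth - call.alt_depth
            record.samples[sample]["AD"] = (ref_depth, call.alt_depth)
            record.samples[sample]["DP"] = call.total_depth
            out.write(record)


def read_bed(path):
    """Read a 3+-column BED of target intervals (0-based half-open)."""
    import pandas as pd

    if os.path.getsize(str(path)) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    return df
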