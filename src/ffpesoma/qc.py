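"""Sequencing-quality control for duplicate-extraction comparisons.

The mismatch-rate statistic subsamples a fixed number of aligned reads
and counts non-polymorphic, high-base-quality mismatches per megabase of
aligned sequence; paired per-sample rates from two extraction protocols
are compared with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam
from pyfaidx import Fasta
from scipy import stats

from .model import PopulationFrequencyTable

__all__ = ["WilcoxonResult", "mismatch_rate", "paired_wilcoxon"]


def mismatch_rate(sam_path, reference: Fasta,
                  population: PopulationFrequencyTable | None = None,
                  min_base_quality: int = 30,
                  n_reads: int = 100_000,
                  seed: int = 0) -> float:
    """High-quality non-polymorphic mismatches per megabase.

    ``n_reads`` aligned reads are subsampled uniformly without
    replacement (seeded); a mismatch counts when its base quality is at
    least ``min_base_quality`` and its reference site is absent from the
    population panel. The rate is mismatches divided by megabases of
    aligned sequence in the subsample.
    """
    polymorphic = population.positions() if population is not None else set()

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        reads = [r for r in sam if not r.is_unmapped]
    if len(reads) < n_reads:
        raise ValueError(
            f"{sam_path}: {len(reads)} aligned reads, need {n_reads} "
            f"({n_reads - len(reads)} short)")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(reads), size=n_reads, replace=False)

    mismatches = 0
    aligned_bases = 0
    ref_cache: dict[str, str] = {}
    for idx in chosen:
        read = reads[idx]
        chrom = read.reference_name
        if chrom not in ref_cache:
            ref_cache[chrom] = str(reference[chrom][:]).upper()
        ref_seq = ref_cache[chrom]
        quals = read.query_qualities
        seq = read.query_sequence
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            aligned_bases += 1
            if seq[qpos] == ref_seq[rpos]:
                continue
            if quals is not None and quals[qpos] < min_base_quality:
                continue
            if (chrom, rpos + 1) in polymorphic:
                continue
            mismatches += 1
    if aligned_bases == 0:
        raise ValueError("no aligned bases in subsample")
    return mismatches / (aligned_bases / 1e6)


@dataclass
class WilcoxonResult:
    statistic: float
    pvalue: float
    n_used: int  # pairs remaining after dropping zero differences
    degenerate: bool = False  # all differences were zero


def paired_wilcoxon(rates_a, rates_b,
                    alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired rate vectors.

    Zero differences are dropped (the classical Wilcoxon convention);
    the exact null distribution is used for n <= 25 and the normal
    approximation with continuity correction above. When every pair is
    tied the result is flagged degenerate with p = 1.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0,
                              degenerate=True)
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=True,
                         alternative=alternative, method=method)
    return WilcoxonResult(statistic=float(res.statistic),
                          pvalue=float(res.pvalue),
                          n_used=int(nonzero.size))
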