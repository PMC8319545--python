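"""Simplified off-target copy-number profiling for targeted panels.

Off-target reads (those not captured by the bait design) sample the
genome approximately uniformly and can be binned into a low-resolution
coverage profile. The pipeline: exclude on-target reads, count read
starts per fixed-width bin, form depth-normalized tumor/normal log2
ratios, segment each chromosome by circular binary segmentation (CBS)
with permutation p-values, re-center the profile on the mode of the
segmented values, and call gains/losses against purity-adjusted log2
cutoffs. Cohort penetrance is the per-bin fraction of samples called
gained (resp. lost).

Bins are 0-based half-open (BED convention) internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Log2Profile",
    "PenetranceTrack",
    "Segment",
    "SegmentedProfile",
    "bin_genome",
    "bin_offtarget_reads",
    "call_gain_loss",
    "compute_log2_ratio",
    "estimate_purity_naive",
    "mode_normalize",
    "penetrance_track",
    "purity_adjusted_cutoffs",
    "segment_profile",
    "select_replicate_by_purity",
]


def bin_genome(chrom_lengths: dict[str, int], bin_size: int) -> pd.DataFrame:
    """Tile each chromosome with fixed-width half-open bins."""
    if bin_size < 1000:
        raise ValueError("bin_size must be >= 1 kb")
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, bin_size):
            rows.append((chrom, start, min(start + bin_size, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.array(merged_s), np.array(merged_e)


def bin_offtarget_reads(read_starts: dict[str, np.ndarray],
                        targets: pd.DataFrame,
                        chrom_lengths: dict[str, int],
                        bin_size: int,
                        read_length: int = 101,
                        margin: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Tally off-target read starts per bin.

    ``read_starts`` maps chromosome to 0-based read start positions;
    a read is on-target (excluded) when its interval
    ``[start, start + read_length)`` overlaps a target interval padded
    by ``margin``. Returns the bin table and the per-bin counts.
    """
    bins = bin_genome(chrom_lengths, bin_size)
    counts = np.zeros(len(bins), dtype=np.int64)
    if targets.empty:
        logger.warning("empty target BED: counting all reads as off-target")
    bin_offset = {chrom: grp.index[0] for chrom, grp in bins.groupby("chrom")}
    for chrom, starts in read_starts.items():
        starts = np.asarray(starts, dtype=np.int64)
        if chrom not in chrom_lengths:
            raise KeyError(f"reads on unknown contig {chrom!r}")
        tgt = targets[targets["chrom"] == chrom]
        if len(tgt):
            tstarts, tends = _merge_intervals(
                tgt["start"].to_numpy() - margin,
                tgt["end"].to_numpy() + margin)
            # read [s, s+L) overlaps [ts, te) iff s < te and s + L > ts
            idx = np.searchsorted(tstarts, starts + read_length, side="left") - 1
            on_target = (idx >= 0) & (starts < tends[np.clip(idx, 0, None)])
            starts = starts[~on_target]
        binned = starts // bin_size + bin_offset[chrom]
        np.add.at(counts, binned, 1)
    return bins, counts


@dataclass
class Log2Profile:
    """Depth-normalized tumor/normal log2 ratio per bin (NaN = masked)."""

    sample_id: str
    bins: pd.DataFrame
    log2: np.ndarray


def compute_log2_ratio(tumor_counts: np.ndarray, normal_counts: np.ndarray,
                       bins: pd.DataFrame, sample_id: str = "") -> Log2Profile:
    """log2((t_i/T) / (n_i/N)) with zero-coverage bins masked to NaN."""
    t = np.asarray(tumor_counts, dtype=float)
    n = np.asarray(normal_counts, dtype=float)
    if t.shape != n.shape or len(t) != len(bins):
        raise ValueError("tumor/normal counts must share the binning")
    T, N = t.sum(), n.sum()
    if T == 0 or N == 0:
        raise ValueError("library size is zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((t / T) / (n / N))
    ratio[(t == 0) | (n == 0)] = np.nan
    return Log2Profile(sample_id=sample_id, bins=bins, log2=ratio)


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    mean: float
    n_bins: int
    bin_indices: np.ndarray  # global bin indices of member bins
    call: str = "neutral"  # gain | neutral | loss


@dataclass
class SegmentedProfile:
    sample_id: str
    bins: pd.DataFrame
    log2: np.ndarray
    segments: list[Segment]
    mode_offset: float = 0.0
    purity: float | None = None


def _max_arc_tstat(x: np.ndarray, min_bins: int) -> float:
    """Largest |t| over admissible circular-arc splits of ``x``.

    An arc [i, j) is admissible when every resulting piece has at least
    ``min_bins`` bins (pieces of size zero, at the ends, are allowed).
    """
    n = len(x)
    s = np.concatenate(([0.0], np.cumsum(x)))
    total = s[-1]
    sd = x.std()
    if sd == 0 or n < 2 * min_bins:
        return 0.0
    i = np.arange(n + 1)
    arc_len = np.subtract.outer(i, i) * -1  # arc_len[a, b] = b - a
    arc_sum = np.subtract.outer(s, s) * -1  # arc_sum[a, b] = s[b] - s[a]
    n1 = arc_len
    n2 = n - n1
    valid = (n1 >= min_bins) & (n2 >= 1)
    # edge pieces: piece [0, a) and [b, n) must be empty or >= min_bins
    a_ok = (i == 0) | (i >= min_bins)
    b_ok = (i == n) | (i <= n - min_bins)
    valid &= a_ok[:, None] & b_ok[None, :]
    valid &= np.triu(np.ones((n + 1, n + 1), dtype=bool), k=1)
    # also require the complement to satisfy min_bins when non-empty
    valid &= (n2 >= min_bins) | (n2 == 0)
    if not valid.any():
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = arc_sum / n1
        mean2 = (total - arc_sum) / np.where(n2 == 0, 1, n2)
        t = np.abs(mean1 - mean2) / (sd * np.sqrt(1.0 / n1 + 1.0 / np.where(n2 == 0, 1, n2)))
    t[~valid] = 0.0
    return float(np.nanmax(t))


def _best_arc(x: np.ndarray, min_bins: int) -> tuple[int, int, float]:
    n = len(x)
    best = (0, n, 0.0)
    s = np.concatenate(([0.0], np.cumsum(x)))
    total = s[-1]
    sd = x.std()
    if sd == 0 or n < 2 * min_bins:
        return best
    for a in range(0, n):
        if a != 0 and a < min_bins:
            continue
        for b in range(a + min_bins, n + 1):
            if b != n and b > n - min_bins:
                continue
            n1 = b - a
            n2 = n - n1
            if n2 == 0 or (n2 < min_bins and n2 != 0):
                continue
            m1 = (s[b] - s[a]) / n1
            m2 = (total - (s[b] - s[a])) / n2
            t = abs(m1 - m2) / (sd * np.sqrt(1.0 / n1 + 1.0 / n2))
            if t > best[2]:
                best = (a, b, t)
    return best


def _segment_chromosome(values: np.ndarray, alpha: float, min_bins: int,
                        n_permutations: int, rng: np.random.Generator
                        ) -> list[tuple[int, int]]:
    """Recursive CBS over one chromosome; returns [start, end) index runs."""

    def recurse(lo: int, hi: int) -> list[tuple[int, int]]:
        x = values[lo:hi]
        a, b, t_obs = _best_arc(x, min_bins)
        if t_obs == 0.0:
            return [(lo, hi)]
        # permutation p-value with early stopping: once enough permuted
        # maxima reach t_obs the split can no longer be significant.
        exceed = 0
        budget = int(np.floor(alpha * (n_permutations + 1))) - 1
        for _ in range(n_permutations):
            perm = rng.permutation(x)
            if _max_arc_tstat(perm, min_bins) >= t_obs:
                exceed += 1
                if exceed > budget:
                    break
        p = (1 + exceed) / (1 + n_permutations)
        if p >= alpha:
            return [(lo, hi)]
        pieces = []
        for s, e in ((lo, lo + a), (lo + a, lo + b), (lo + b, hi)):
            if e > s:
                pieces.extend(recurse(s, e))
        return pieces

    return recurse(0, len(values))


def segment_profile(profile: Log2Profile, alpha: float = 0.01,
                    min_bins: int = 5, n_permutations: int = 1000,
                    seed: int = 0) -> SegmentedProfile:
    """Segment each chromosome by CBS with permutation p-values.

    Masked (NaN) bins are dropped before segmentation; segment
    boundaries are reported in genomic coordinates of the member bins.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    bins = profile.bins
    for chrom in bins["chrom"].unique():
        sel = (bins["chrom"] == chrom).to_numpy() & ~np.isnan(profile.log2)
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            continue
        values = profile.log2[idx]
        for lo, hi in _segment_chromosome(values, alpha, min_bins,
                                          n_permutations, rng):
            members = idx[lo:hi]
            segments.append(Segment(
                chrom=chrom,
                start=int(bins["start"].iloc[members[0]]),
                end=int(bins["end"].iloc[members[-1]]),
                mean=float(values[lo:hi].mean()),
                n_bins=int(hi - lo),
                bin_indices=members,
            ))
    return SegmentedProfile(sample_id=profile.sample_id, bins=bins,
                            log2=profile.log2.copy(), segments=segments)


def weighted_mode_offset(means, weights, width: float = 0.05) -> float:
    """Mode of segment means: densest ``width``-wide histogram bin
    (centers at multiples of ``width``), weighted by segment length;
    ties resolved toward 0."""
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    centers = np.round(means / width).astype(int)
    tally: dict[int, float] = {}
    for c, w in zip(centers, weights):
        tally[c] = tally.get(c, 0.0) + w
    best_weight = max(tally.values())
    candidates = [c for c, w in tally.items() if w == best_weight]
    if len(candidates) > 1:
        logger.info("mode tie between %s; choosing nearest 0",
                    [c * width for c in candidates])
    chosen = min(candidates, key=lambda c: (abs(c * width), c * width))
    return chosen * width


def mode_normalize(segmented: SegmentedProfile,
                   width: float = 0.05) -> SegmentedProfile:
    """Re-center the profile on the mode of the segmented values.

    Most of a tumor genome is copy-neutral, so the densest cluster of
    segment means (weighted by segment length) estimates the neutral
    level; it is subtracted from every segment mean and bin ratio.
    """
    if not segmented.segments:
        raise ValueError("profile has no segments")
    offset = weighted_mode_offset(
        [s.mean for s in segmented.segments],
        [s.n_bins for s in segmented.segments], width)
    new_segments = [replace(s, mean=s.mean - offset)
                    for s in segmented.segments]
    return SegmentedProfile(
        sample_id=segmented.sample_id, bins=segmented.bins,
        log2=segmented.log2 - offset, segments=new_segments,
        mode_offset=offset, purity=segmented.purity)


def purity_adjusted_cutoffs(purity: float,
                            calling_factor: float = 0.5
                            ) -> tuple[float, float]:
    """Log2-ratio cutoffs for gain/loss calls at a given tumor purity.

    In a diploid admixture with tumor fraction p, a single-copy gain
    shifts the expected ratio to log2(1 + p/2) and a single-copy loss to
    log2(1 - p/2); calling cutoffs are ``calling_factor`` times those
    full-change values so that subclonal or noisy events still call.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    gain_full = np.log2(1 + purity / 2)
    loss_full = np.log2(1 - purity / 2)
    return float(calling_factor * gain_full), float(calling_factor * loss_full)


def call_gain_loss(segmented: SegmentedProfile,
                   cutoffs: tuple[float, float]) -> SegmentedProfile:
    """Call each segment gain/neutral/loss against the log2 cutoffs."""
    gain_cut, loss_cut = cutoffs
    called = [replace(s, call=("gain" if s.mean >= gain_cut
                               else "loss" if s.mean <= loss_cut
                               else "neutral"))
              for s in segmented.segments]
    return replace(segmented, segments=called)


@dataclass
class PenetranceTrack:
    """Per-bin fraction of cohort samples called gain / loss."""

    bins: pd.DataFrame
    gain_fraction: np.ndarray
    loss_fraction: np.ndarray
    n_samples: int = 0

    def as_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["gain_fraction"] = self.gain_fraction
        out["loss_fraction"] = self.loss_fraction
        return out


def penetrance_track(profiles: list[SegmentedProfile]) -> PenetranceTrack:
    """Cohort penetrance from called (normalized) profiles."""
    if not profiles:
        raise ValueError("no profiles")
    bins = profiles[0].bins
    gain = np.zeros(len(bins))
    loss = np.zeros(len(bins))
    for profile in profiles:
        if len(profile.bins) != len(bins):
            raise ValueError("profiles must share the binning")
        for seg in profile.segments:
            if seg.call == "gain":
                gain[seg.bin_indices] += 1
            elif seg.call == "loss":
                loss[seg.bin_indices] += 1
    n = len(profiles)
    return PenetranceTrack(bins=bins, gain_fraction=gain / n,
                           loss_fraction=loss / n, n_samples=n)


def select_replicate_by_purity(purities: dict[str, float]) -> str:
    """Pick the replicate with the highest purity estimate for
    downstream analysis; ties break lexicographically (logged)."""
    if not purities:
        raise ValueError("no purity estimates; run estimate_purity_naive "
                         "or supply purities")
    best = max(purities.values())
    winners = sorted(k for k, v in purities.items() if v == best)
    if len(winners) > 1:
        logger.info("purity tie among %s; choosing %s", winners, winners[0])
    return winners[0]


def estimate_purity_naive(vafs) -> float:
    """Crude purity estimate: twice the median somatic VAF (clonal
    heterozygous model), clipped to (0.05, 1.0]. Needs >= 5 SNVs."""
    vafs = np.asarray(list(vafs), dtype=float)
    if vafs.size < 5:
        raise ValueError(f"need >= 5 somatic SNVs, got {vafs.size}")
    return float(np.clip(2 * np.median(vafs), 0.05, 1.0))
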