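"""Synthetic duplicate-core FFPE panel-sequencing cohorts with known truth.

The generator emulates the statistical structure of the real study
design — duplicate FFPE cores per tumor extracted with two kits, a
primary tumor/normal SNV caller, a raw permissive secondary caller, an
indel caller, concurrent cardiac/splenic tumor pairs, and a reference
population panel — so that every downstream stage can be tested, end to
end, against a planted truth table and without any download.

Planted classes per sample:

* ``true_somatic`` — present in both replicates' primary calls with
  correlated VAFs (shared underlying cell fraction, independent
  sequencing noise) and in the secondary caller; concurrent pairs share
  a configurable fraction of keys.
* ``germline`` — population-panel variants (AF >= 1%) leaking into the
  tumor call sets at heterozygous VAF.
* ``deamination_artifact`` — low-VAF C>T/G>A drawn independently per
  replicate, so replicate concordance separates them from real events.
* ``oxidation_artifact`` — low-VAF C>A at CCN/TCN contexts (or G>T at
  NGG/NGA), the OxoG damage mode, also independent per replicate.
* ``recurrent_artifact`` — cohort-wide positions emitted into the raw
  secondary calls of many samples at homogeneous low VAF, and into the
  primary calls of at most one.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from array import array
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .io import open_reference, reverse_complement
from .model import (
    BASES,
    CallerRole,
    GenomicVariant,
    PopulationFrequencyTable,
    SampleMeta,
    VariantCall,
)
from .filtering import CohortCalls
from .scna import Log2Profile, bin_genome

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "TruthRecord",
    "generate_reference",
    "generate_cohort",
    "generate_reads",
    "simulate_log2_profiles",
    "write_run_directory",
]

# gene symbols for the synthetic gene map: recurrent drivers observed in
# vascular sarcomas plus germline risk genes and filler cancer genes
GENE_NAMES = (
    "TP53", "PIK3CA", "ATRX", "LRP1B", "GRIN2A", "NFATC2", "NOTCH1",
    "PRKDC", "RELN", "PTPRD", "FAT1", "ARHGEF28", "DCTN1", "EP400",
    "ERCC2", "IRS2", "PIK3R1", "RASA1", "SMAD4", "SNCAIP", "TRRAP",
    "IDH1", "IDH2", "POT1", "PTEN", "RB1", "XPC", "KMT2D", "ERBB4",
    "PLCG2", "SMARCA1", "KDR", "MTOR", "SETD2", "TERT", "GLI1", "PGR",
    "PCLO", "KLHL6", "LATS2", "CALR", "BIRC3", "PAX3", "TEK", "ROBO1",
    "PTPRB", "PTPRO", "PTPRS", "PTPRT", "NOTCH2", "PIK3C2G", "PIK3C2B",
    "EGFR", "BRAF", "KRAS", "NRAS", "ALK", "MYC", "CDKN2A", "VHL",
)

_CONSEQUENCES = ("missense", "nonsense", "synonymous", "splice_region")
_CONSEQUENCE_P = (0.60, 0.10, 0.20, 0.10)
_PROTEIN_ALTERING = {"missense", "nonsense", "frameshift", "inframe"}


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic cohort.

    Cohort sizes mirror the real study (15 canine visceral patients, 14
    of them with concurrent cardiac+splenic lesions; 13 canine and 13
    feline skin patients), sequencing depth is negative-binomial around
    300x (the study's median target coverage was ~300-fold), and every
    tumor is sequenced as two extraction replicates.
    """

    seed: int = 0
    # cohort structure
    n_visceral_patients: int = 15
    n_concurrent_pairs: int = 14
    n_canine_skin_patients: int = 13
    n_feline_skin_patients: int = 13
    # reference
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    # mutation load per tumor
    n_true_somatic: int = 30
    n_true_indels: int = 3
    shared_fraction: float = 0.8
    n_rescue_sites: int = 2  # true somatics missed by primary in one replicate
    # artifact load per replicate
    n_deamination_artifacts: int = 150
    n_oxidation_artifacts: int = 80
    # cohort-wide systematic artifacts
    n_recurrent_artifact_sites: int = 20
    recurrent_sample_fraction: float = 0.10
    recurrent_carrier_fraction: float = 0.25
    # population panel
    n_population_variants: int = 200
    n_germline_leaks: int = 3
    # germline call sets (per patient, for the risk screen)
    n_germline_variants: int = 40
    # UV-signature samples (first of the canine skin cohort)
    n_uv_samples: int = 3
    n_uv_mutations: int = 500
    # distributions
    depth_mean: float = 300.0
    depth_size: float = 50.0  # negative-binomial size parameter
    true_vaf_alpha: float = 5.0  # Beta(5, 15): mean 0.25
    true_vaf_beta: float = 15.0
    # deamination VAF = 0.01 + 0.05 * Beta(1.2, 8): mass concentrated
    # well below the high-confidence VAF bar
    deamination_vaf_range: tuple[float, float] = (0.01, 0.06)
    deamination_beta: tuple[float, float] = (1.2, 8.0)
    # oxidation VAF = 0.01 + 0.07 * Beta(1.5, 3): support within the
    # oxidation filter's <= 0.10 window even after sequencing noise
    oxidation_vaf_range: tuple[float, float] = (0.01, 0.08)
    oxidation_beta: tuple[float, float] = (1.5, 3.0)
    n_genes: int = 60
    replicate_ids: tuple[str, ...] = ("r1", "r2")
    extraction_kits: tuple[str, ...] = ("qiaamp", "generead")

    def __post_init__(self) -> None:
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.chrom_length < 1000:
            raise ValueError("chrom_length must be >= 1000")
        for name in ("n_true_somatic", "n_true_indels",
                     "n_deamination_artifacts", "n_oxidation_artifacts",
                     "n_recurrent_artifact_sites", "n_population_variants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Generator label for one planted variant in one sample."""

    variant: GenomicVariant
    sample_id: str
    truth_class: str  # true_somatic | germline | deamination_artifact |
    #                   oxidation_artifact | recurrent_artifact
    planted_vaf: float

    CLASSES = ("true_somatic", "germline", "deamination_artifact",
               "oxidation_artifact", "recurrent_artifact")


@dataclass
class SyntheticCohort:
    """Everything a downstream stage needs, with the truth attached."""

    config: GeneratorConfig
    reference_path: str
    chrom_lengths: dict[str, int]
    cohort: CohortCalls
    truth: list[TruthRecord]
    population: PopulationFrequencyTable
    germline_calls: dict[str, list[VariantCall]]  # patient -> germline-mode calls
    gene_map: "GeneMap"

    def truth_by_sample(self) -> dict[str, dict[GenomicVariant, TruthRecord]]:
        out: dict[str, dict[GenomicVariant, TruthRecord]] = {}
        for rec in self.truth:
            out.setdefault(rec.sample_id, {})[rec.variant] = rec
        return out

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.sample_id, t.variant.chrom, t.variant.pos, t.variant.ref,
              t.variant.alt, t.truth_class, t.planted_vaf)
             for t in self.truth],
            columns=["sample_id", "chrom", "pos", "ref", "alt",
                     "truth_class", "planted_vaf"])


class GeneMap:
    """Even partition of the synthetic genome into named gene intervals."""

    def __init__(self, chrom_lengths: dict[str, int], n_genes: int,
                 names: tuple[str, ...] = GENE_NAMES):
        self.intervals: list[tuple[str, int, int, str]] = []
        chroms = list(chrom_lengths)
        per_chrom = max(1, n_genes // len(chroms))
        idx = 0
        for chrom in chroms:
            length = chrom_lengths[chrom]
            width = length // per_chrom
            for g in range(per_chrom):
                start = g * width + 1
                end = length if g == per_chrom - 1 else (g + 1) * width
                self.intervals.append(
                    (chrom, start, end, names[idx % len(names)]))
                idx += 1

    def gene_at(self, chrom: str, pos: int) -> str:
        for c, start, end, name in self.intervals:
            if c == chrom and start <= pos <= end:
                return name
        return ""

    def positions_of(self, gene: str) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, s, e, n in self.intervals if n == gene]


def generate_reference(config: GeneratorConfig, path) -> dict[str, int]:
    """Write a uniform-random FASTA (+ .fai index); returns contig lengths.

    Deterministic per seed: the same config writes byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    path = str(path)
    lengths: dict[str, int] = {}
    with open(path, "w") as out:
        for c in range(config.n_chromosomes):
            chrom = f"chr{c + 1}"
            lengths[chrom] = config.chrom_length
            seq = "".join(np.array(list(BASES))[
                rng.integers(0, 4, config.chrom_length)])
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i:i + 70] + "\n")
    open_reference(path)  # build the .fai
    return lengths


class _ContextIndex:
    """Per-context position lookup over the reference, for planting
    variants with prescribed sequence context."""

    def __init__(self, reference_path: str):
        fasta = open_reference(reference_path)
        self.seq = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
        self.by_base: dict[str, list[tuple[str, int]]] = {b: [] for b in BASES}
        # pyrimidine-centered trinucleotide -> positions (either strand);
        # entries are (chrom, pos, strand) with strand "+" when the
        # pyrimidine is on the reference strand.
        self.by_context: dict[str, list[tuple[str, int, str]]] = {}
        for chrom, seq in self.seq.items():
            arr = np.frombuffer(seq.encode(), dtype="S1")
            for base in BASES:
                positions = np.flatnonzero(arr == base.encode()) + 1
                self.by_base[base].extend((chrom, int(p)) for p in positions)
            for i in range(1, len(seq) - 1):
                tri = seq[i - 1:i + 2]
                center = tri[1]
                if center in "CT":
                    self.by_context.setdefault(tri, []).append(
                        (chrom, i + 1, "+"))
                else:
                    self.by_context.setdefault(
                        reverse_complement(tri), []).append((chrom, i + 1, "-"))

    def base_at(self, chrom: str, pos: int) -> str:
        return self.seq[chrom][pos - 1]

    def oxidation_sites(self) -> list[tuple[str, int, str]]:
        """Positions eligible for OxoG planting: pyrimidine-strand
        context CCN or TCN (strand '-' entries are NGG/NGA sites where
        the artifact appears as G>T)."""
        sites = []
        for tri, entries in self.by_context.items():
            if tri[1] == "C" and tri[0] in "CT":
                sites.extend(entries)
        return sites


def _draw_depth(rng: np.random.Generator, config: GeneratorConfig) -> int:
    r, mu = config.depth_size, config.depth_mean
    return max(30, int(rng.negative_binomial(r, r / (r + mu))))


def _emit(rng, config, variant, sample_id, rep, role, vaf,
          gene_map: GeneMap, consequence: str | None = None,
          exact_vaf: bool = False) -> VariantCall:
    depth = _draw_depth(rng, config)
    if exact_vaf:  # realize the planted VAF without sampling noise
        alt = int(np.clip(round(vaf * depth), 1, depth))
    else:
        alt = int(np.clip(rng.binomial(depth, vaf), 1, depth))
    gene = gene_map.gene_at(variant.chrom, variant.pos)
    if consequence is None:
        consequence = str(rng.choice(_CONSEQUENCES, p=_CONSEQUENCE_P))
    return VariantCall(
        variant=variant, sample_id=sample_id, replicate_id=rep,
        caller_role=role, alt_depth=alt, total_depth=depth,
        vaf=alt / depth, gene=gene, consequence=consequence,
        is_protein_altering=consequence in _PROTEIN_ALTERING)


def _random_snv(rng, ctx: _ContextIndex, reserved: set[tuple[str, int]],
                chrom_lengths: dict[str, int]) -> GenomicVariant:
    while True:
        chrom = str(rng.choice(list(chrom_lengths)))
        pos = int(rng.integers(2, chrom_lengths[chrom] - 1))
        if (chrom, pos) in reserved:
            continue
        ref = ctx.base_at(chrom, pos)
        alt = str(rng.choice([b for b in BASES if b != ref]))
        return GenomicVariant(chrom, pos, ref, alt)


def _random_indel(rng, ctx: _ContextIndex, reserved: set[tuple[str, int]],
                  chrom_lengths: dict[str, int]) -> GenomicVariant:
    while True:
        chrom = str(rng.choice(list(chrom_lengths)))
        pos = int(rng.integers(2, chrom_lengths[chrom] - 10))
        if (chrom, pos) in reserved:
            continue
        anchor = ctx.base_at(chrom, pos)
        if rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 4))))
            return GenomicVariant(chrom, pos, anchor, anchor + ins)
        size = int(rng.integers(1, 4))
        deleted = ctx.seq[chrom][pos - 1: pos + size]
        return GenomicVariant(chrom, pos, deleted, anchor)


def _deamination_variant(rng, ctx: _ContextIndex,
                         used: set[tuple[str, int]]) -> GenomicVariant:
    # C>T on one strand, G>A on the other, with equal probability
    base = "C" if rng.random() < 0.5 else "G"
    alt = "T" if base == "C" else "A"
    sites = ctx.by_base[base]
    while True:
        chrom, pos = sites[int(rng.integers(len(sites)))]
        if (chrom, pos) not in used:
            return GenomicVariant(chrom, pos, base, alt)


def _oxidation_variant(rng, sites, used: set[tuple[str, int]]) -> GenomicVariant:
    while True:
        chrom, pos, strand = sites[int(rng.integers(len(sites)))]
        if (chrom, pos) in used:
            continue
        if strand == "+":
            return GenomicVariant(chrom, pos, "C", "A")
        return GenomicVariant(chrom, pos, "G", "T")


def _uv_variant(rng, ctx: _ContextIndex, profile_channels, profile_weights,
                used: set[tuple[str, int]]) -> GenomicVariant:
    """Plant a C>T (or strand-mirrored G>A) at a context drawn from a
    UV-like channel profile."""
    while True:
        label = profile_channels[int(rng.choice(
            len(profile_channels), p=profile_weights))]
        tri = label[0] + label[2] + label[6]  # five + ref + three
        entries = ctx.by_context.get(tri, [])
        if not entries:
            continue
        chrom, pos, strand = entries[int(rng.integers(len(entries)))]
        if (chrom, pos) in used:
            continue
        if strand == "+":
            return GenomicVariant(chrom, pos, "C", "T")
        return GenomicVariant(chrom, pos, "G", "A")


def _build_manifest(config: GeneratorConfig) -> list[SampleMeta]:
    samples: list[SampleMeta] = []

    def add(sample_id, patient_id, species, tissue, cohort):
        samples.append(SampleMeta(
            sample_id=sample_id, patient_id=patient_id, species=species,
            tissue=tissue, cohort=cohort,
            extraction_kit="+".join(config.extraction_kits),
            replicate_ids=list(config.replicate_ids)))

    for i in range(config.n_visceral_patients):
        pid = f"DV{i + 1:03d}"
        add(f"{pid}_cardiac", pid, "canine", "cardiac", "canine_visceral")
        if i < config.n_concurrent_pairs:
            add(f"{pid}_splenic", pid, "canine", "splenic", "canine_visceral")
    for i in range(config.n_canine_skin_patients):
        pid = f"DS{i + 1:03d}"
        add(f"{pid}_skin", pid, "canine", "skin", "canine_skin")
    for i in range(config.n_feline_skin_patients):
        pid = f"FS{i + 1:03d}"
        add(f"{pid}_skin", pid, "feline", "skin", "feline_skin")
    return samples


def generate_cohort(config: GeneratorConfig,
                    reference_path) -> SyntheticCohort:
    """Generate call sets, manifest, truth table and population table."""
    from .signatures import synthetic_signature_catalog

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ctx = _ContextIndex(str(reference_path))
    chrom_lengths = {c: len(s) for c, s in ctx.seq.items()}
    gene_map = GeneMap(chrom_lengths, config.n_genes)
    manifest = _build_manifest(config)
    oxidation_sites = ctx.oxidation_sites()
    for name, demand, supply in (
            ("oxidation", config.n_oxidation_artifacts, len(oxidation_sites)),
            ("deamination", config.n_deamination_artifacts,
             len(ctx.by_base["C"]) + len(ctx.by_base["G"]))):
        if demand > supply:
            raise ValueError(
                f"{name}: {demand} artifact sites demanded, only {supply} "
                "eligible context positions in the reference")

    calls: dict[tuple[str, str, CallerRole], list[VariantCall]] = {}
    truth: list[TruthRecord] = []
    germline_calls: dict[str, list[VariantCall]] = {}

    def bucket(sample_id, rep, role) -> list[VariantCall]:
        return calls.setdefault((sample_id, rep, role), [])

    # ---- population panel ------------------------------------------------
    population = PopulationFrequencyTable()
    reserved: set[tuple[str, int]] = set()
    common_pool: list[GenomicVariant] = []
    for i in range(config.n_population_variants):
        v = _random_snv(rng, ctx, reserved, chrom_lengths)
        reserved.add((v.chrom, v.pos))
        if i % 2 == 0:  # common variants, at/above the 1% filter cutoff
            af = float(rng.uniform(0.01, 0.5))
            common_pool.append(v)
        else:  # rare variants, below the cutoff
            af = float(rng.uniform(0.0005, 0.009))
        population[v] = af

    # ---- cohort-wide recurrent artifact sites ----------------------------
    sample_ids = [s.sample_id for s in manifest]
    n_samples = len(sample_ids)
    recurrent_sites: list[tuple[GenomicVariant, list[str], str | None]] = []
    for i in range(config.n_recurrent_artifact_sites):
        v = _random_snv(rng, ctx, reserved, chrom_lengths)
        reserved.add((v.chrom, v.pos))
        n_carriers = max(
            math.ceil(config.recurrent_sample_fraction * n_samples) + 1,
            round(config.recurrent_carrier_fraction * n_samples))
        carriers = list(rng.choice(sample_ids, size=n_carriers, replace=False))
        # half the sites also hit the primary caller of one sample
        victim = None
        if i % 2 == 0:
            others = [s for s in sample_ids if s not in carriers]
            victim = str(rng.choice(others))
        recurrent_sites.append((v, [str(c) for c in carriers], victim))

    # ---- UV channel profile (SBS7a-like stand-in) ------------------------
    catalog = synthetic_signature_catalog()
    uv_vector = catalog.vector("SBS7a")
    uv_channels = [c for c, w in zip(catalog.profiles.index, uv_vector) if w > 0]
    uv_weights = uv_vector[uv_vector > 0]
    uv_weights = uv_weights / uv_weights.sum()
    uv_sample_ids = {
        s.sample_id for s in manifest if s.cohort == "canine_skin"
    }
    uv_sample_ids = set(sorted(uv_sample_ids)[: config.n_uv_samples])

    # ---- per-patient germline + tumors -----------------------------------
    by_patient: dict[str, list[SampleMeta]] = {}
    for s in manifest:
        by_patient.setdefault(s.patient_id, []).append(s)

    for patient_id, tumors in by_patient.items():
        # germline call set (germline-mode secondary caller on the normal)
        germline = []
        for _ in range(config.n_germline_variants):
            v = _random_snv(rng, ctx, reserved, chrom_lengths)
            vaf = 0.5 if rng.random() < 0.7 else 1.0
            germline.append(_emit(rng, config, v, patient_id, "normal",
                                  CallerRole.SECONDARY_RAW, vaf, gene_map))
        germline_calls[patient_id] = germline

        # patient-level somatic pool; concurrent pairs share a fraction
        pool_size = config.n_true_somatic + config.n_true_indels
        shared_n = round(config.shared_fraction * pool_size) \
            if len(tumors) > 1 else 0
        shared_keys: list[GenomicVariant] = []
        for j in range(shared_n):
            maker = _random_indel if j < round(
                config.shared_fraction * config.n_true_indels) else _random_snv
            v = maker(rng, ctx, reserved, chrom_lengths)
            shared_keys.append(v)

        for tumor in tumors:
            sid = tumor.sample_id
            used: set[tuple[str, int]] = set(reserved)
            used.update((v.chrom, v.pos) for v in shared_keys)
            private_n = pool_size - len(shared_keys)
            keys = list(shared_keys)
            n_private_indels = config.n_true_indels - sum(
                1 for k in keys if k.is_indel)
            for j in range(private_n):
                maker = _random_indel if j < n_private_indels else _random_snv
                v = maker(rng, ctx, used, chrom_lengths)
                keys.append(v)
            if sid in uv_sample_ids:
                for _ in range(config.n_uv_mutations):
                    keys.append(_uv_variant(rng, ctx, uv_channels,
                                            uv_weights, used))
            # rescue sites: primary misses them in one replicate
            n_rescue = min(config.n_rescue_sites, len(keys))
            rescue_idx = set(rng.choice(len(keys), size=n_rescue,
                                        replace=False)) if n_rescue else set()
            for j, v in enumerate(keys):
                used.add((v.chrom, v.pos))
                vaf = float(rng.beta(config.true_vaf_alpha,
                                     config.true_vaf_beta))
                truth.append(TruthRecord(v, sid, "true_somatic", vaf))
                consequence = None
                miss_rep = (str(rng.choice(config.replicate_ids))
                            if j in rescue_idx else None)
                for rep in config.replicate_ids:
                    role = (CallerRole.INDEL if v.is_indel
                            else CallerRole.PRIMARY_SNV)
                    call = _emit(rng, config, v, sid, rep, role, vaf,
                                 gene_map, consequence)
                    consequence = call.consequence  # stable across reps/tumors
                    if rep != miss_rep:
                        bucket(sid, rep, role).append(call)
                    # the permissive secondary caller always sees it
                    if not v.is_indel:
                        bucket(sid, rep, CallerRole.SECONDARY_RAW).append(
                            call.with_role(CallerRole.SECONDARY_RAW))

            # germline leakage from the common population pool
            leaks = rng.choice(len(common_pool),
                               size=min(config.n_germline_leaks,
                                        len(common_pool)), replace=False)
            for li in leaks:
                v = common_pool[int(li)]
                truth.append(TruthRecord(v, sid, "germline", 0.5))
                for rep in config.replicate_ids:
                    call = _emit(rng, config, v, sid, rep,
                                 CallerRole.PRIMARY_SNV, 0.5, gene_map)
                    bucket(sid, rep, CallerRole.PRIMARY_SNV).append(call)
                    bucket(sid, rep, CallerRole.SECONDARY_RAW).append(
                        call.with_role(CallerRole.SECONDARY_RAW))

            # replicate-independent FFPE artifacts
            lo_d, hi_d = config.deamination_vaf_range
            a_d, b_d = config.deamination_beta
            lo_o, hi_o = config.oxidation_vaf_range
            a_o, b_o = config.oxidation_beta
            for rep in config.replicate_ids:
                rep_used = set(used)
                for _ in range(config.n_deamination_artifacts):
                    v = _deamination_variant(rng, ctx, rep_used)
                    rep_used.add((v.chrom, v.pos))
                    vaf = lo_d + (hi_d - lo_d) * float(rng.beta(a_d, b_d))
                    truth.append(TruthRecord(v, sid, "deamination_artifact",
                                             vaf))
                    call = _emit(rng, config, v, sid, rep,
                                 CallerRole.PRIMARY_SNV, vaf, gene_map)
                    bucket(sid, rep, CallerRole.PRIMARY_SNV).append(call)
                    bucket(sid, rep, CallerRole.SECONDARY_RAW).append(
                        call.with_role(CallerRole.SECONDARY_RAW))
                for _ in range(config.n_oxidation_artifacts):
                    v = _oxidation_variant(rng, oxidation_sites, rep_used)
                    rep_used.add((v.chrom, v.pos))
                    vaf = lo_o + (hi_o - lo_o) * float(rng.beta(a_o, b_o))
                    truth.append(TruthRecord(v, sid, "oxidation_artifact",
                                             vaf))
                    call = _emit(rng, config, v, sid, rep,
                                 CallerRole.PRIMARY_SNV, vaf, gene_map)
                    bucket(sid, rep, CallerRole.PRIMARY_SNV).append(call)
                    bucket(sid, rep, CallerRole.SECONDARY_RAW).append(
                        call.with_role(CallerRole.SECONDARY_RAW))

    # ---- recurrent-site emissions ----------------------------------------
    for v, carriers, victim in recurrent_sites:
        for sid in carriers:
            # homogeneous low-VAF stratum: realized exactly, so every
            # carrier observation stays below the VAF split
            vaf = float(rng.uniform(0.015, 0.045))
            truth.append(TruthRecord(v, sid, "recurrent_artifact", vaf))
            for rep in config.replicate_ids:
                bucket(sid, rep, CallerRole.SECONDARY_RAW).append(
                    _emit(rng, config, v, sid, rep,
                          CallerRole.SECONDARY_RAW, vaf, gene_map,
                          exact_vaf=True))
        if victim is not None:
            vaf = float(rng.uniform(0.15, 0.35))
            truth.append(TruthRecord(v, victim, "recurrent_artifact", vaf))
            for rep in config.replicate_ids:
                call = _emit(rng, config, v, victim, rep,
                             CallerRole.PRIMARY_SNV, vaf, gene_map)
                bucket(victim, rep, CallerRole.PRIMARY_SNV).append(call)
                bucket(victim, rep, CallerRole.SECONDARY_RAW).append(
                    call.with_role(CallerRole.SECONDARY_RAW))

    # deduplicate truth: one record per (sample, key), first class wins
    seen: set[tuple[str, GenomicVariant]] = set()
    unique_truth = []
    for rec in truth:
        ident = (rec.sample_id, rec.variant)
        if ident not in seen:
            seen.add(ident)
            unique_truth.append(rec)

    return SyntheticCohort(
        config=config, reference_path=str(reference_path),
        chrom_lengths=chrom_lengths,
        cohort=CohortCalls(samples=manifest, calls=calls),
        truth=unique_truth, population=population,
        germline_calls=germline_calls, gene_map=gene_map)


def generate_reads(config: GeneratorConfig, reference_path,
                   mismatch_rate_per_mb: float, path,
                   n_reads: int = 100_000, read_length: int = 101,
                   decoy_rate_per_mb: float | None = None,
                   polymorphic_sites: set[tuple[str, int]] | None = None,
                   seed_offset: int = 0) -> None:
    """Write a SAM of aligned reads with planted mismatches.

    High-quality (Q >= 30) mismatches are planted at the requested rate
    per megabase of aligned sequence; low-quality (Q < 30) decoy
    mismatches are planted at ``decoy_rate_per_mb`` (default: twice the
    main rate plus 50/Mb) and must be excluded by the QC. When
    ``polymorphic_sites`` is given, additional high-quality mismatches
    are planted there, which the non-polymorphic QC must also exclude.
    """
    if mismatch_rate_per_mb < 0:
        raise ValueError("mismatch rate must be >= 0")
    if decoy_rate_per_mb is None:
        decoy_rate_per_mb = 2 * mismatch_rate_per_mb + 50
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2, seed_offset]))
    fasta = open_reference(str(reference_path))
    chroms = list(fasta.keys())
    seqs = {c: str(fasta[c][:]).upper() for c in chroms}
    lengths = {c: len(seqs[c]) for c in chroms}
    poly_by_chrom: dict[str, np.ndarray] = {}
    if polymorphic_sites:
        for c in chroms:
            poly_by_chrom[c] = np.array(
                sorted(p for ch, p in polymorphic_sites if ch == c))

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": lengths[c]} for c in chroms]}
    p_hi = mismatch_rate_per_mb * read_length / 1e6
    p_lo = decoy_rate_per_mb * read_length / 1e6
    other = {b: [x for x in BASES if x != b] for b in BASES}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(n_reads):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, lengths[chrom] - read_length))
            bases = list(seqs[chrom][start:start + read_length])
            quals = np.full(read_length, 35, dtype=np.int32)
            for p, qual in ((p_hi, 35), (p_lo, 20)):
                for _ in range(rng.poisson(p)):
                    off = int(rng.integers(read_length))
                    refpos = start + off + 1
                    if poly_by_chrom.get(chrom) is not None and np.isin(
                            refpos, poly_by_chrom[chrom]):
                        continue
                    bases[off] = str(rng.choice(other[bases[off]]))
                    quals[off] = qual
            # planted polymorphic-site mismatches (high quality)
            if polymorphic_sites and rng.random() < 0.02:
                sites = poly_by_chrom.get(chrom)
                if sites is not None and len(sites):
                    inside = sites[(sites > start) &
                                   (sites <= start + read_length)]
                    if len(inside):
                        off = int(inside[0]) - start - 1
                        bases[off] = str(rng.choice(other[bases[off]]))
                        quals[off] = 35
            read = pysam.AlignedSegment()
            read.query_name = f"r{i:07d}"
            read.query_sequence = "".join(bases)
            read.flag = 0
            read.reference_id = chroms.index(chrom)
            read.reference_start = start
            read.mapping_quality = 60
            read.cigarstring = f"{read_length}M"
            read.query_qualities = array("B", [int(q) for q in quals])
            out.write(read)


def simulate_log2_profiles(n_samples: int, chrom_lengths: dict[str, int],
                           bin_size: int, events, noise_sd: float = 0.05,
                           seed: int = 0) -> list[Log2Profile]:
    """Noisy log2 profiles with planted copy-number events.

    ``events`` is a list of (sample_indices, chrom, start_bin, end_bin,
    delta): the delta is added to the given bin range (within the
    chromosome) of each listed sample.
    """
    rng = np.random.default_rng(seed)
    bins = bin_genome(chrom_lengths, bin_size)
    profiles = []
    chrom_first = {c: g.index[0] for c, g in bins.groupby("chrom")}
    for s in range(n_samples):
        values = rng.normal(0.0, noise_sd, len(bins))
        for sample_indices, chrom, b0, b1, delta in events:
            if s in sample_indices:
                base = chrom_first[chrom]
                values[base + b0: base + b1] += delta
        profiles.append(Log2Profile(sample_id=f"S{s + 1:03d}", bins=bins,
                                    log2=values))
    return profiles


def write_run_directory(synthetic: SyntheticCohort, outdir) -> None:
    """Write the cohort to disk: per-(sample, replicate, role) VCFs, the
    manifest, truth and population TSVs, and a config echo."""
    import dataclasses
    import json
    import os

    from .io import write_vcf
    from .model import write_manifest

    outdir = str(outdir)
    os.makedirs(os.path.join(outdir, "vcf"), exist_ok=True)
    write_manifest(synthetic.cohort.samples,
                   os.path.join(outdir, "manifest.tsv"))
    synthetic.truth_frame().to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    synthetic.population.to_tsv(os.path.join(outdir, "population.tsv"))
    for (sample_id, rep, role), call_list in synthetic.cohort.calls.items():
        ordered = sorted(call_list,
                         key=lambda c: (c.variant.chrom, c.variant.pos,
                                        c.variant.ref, c.variant.alt))
        write_vcf(ordered,
                  os.path.join(outdir, "vcf",
                               f"{sample_id}.{rep}.{role.value}.vcf"),
                  contig_lengths=synthetic.chrom_lengths)
    config = dataclasses.asdict(synthetic.config)
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=list)
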