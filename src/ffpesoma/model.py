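"""Core domain types shared by every stage of the pipeline.

Coordinates follow the VCF convention throughout: 1-based, fully closed,
with ``pos`` pointing at the first reference base of the variant. All
modules exchange :class:`GenomicVariant` / :class:`VariantCall` objects,
never raw tuples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "BASES",
    "CallerRole",
    "FILTER_PASS",
    "FILTER_OXIDATION",
    "FILTER_LOW_CONFIDENCE",
    "FILTER_INDEL_LOW_VAF",
    "FILTER_POPULATION",
    "FILTER_RECURRENT",
    "FILTER_RESCUED",
    "FILTER_VOCABULARY",
    "FilterConfig",
    "GenomicVariant",
    "PopulationFrequencyTable",
    "SampleMeta",
    "VariantCall",
    "load_manifest",
    "write_manifest",
]

BASES = "ACGT"

# FILTER column vocabulary (bit-exact strings used in written VCFs).
FILTER_PASS = "PASS"
FILTER_OXIDATION = "oxidation_artifact"
FILTER_LOW_CONFIDENCE = "low_confidence"
FILTER_INDEL_LOW_VAF = "indel_low_vaf"
FILTER_POPULATION = "population"
FILTER_RECURRENT = "recurrent_artifact"
FILTER_RESCUED = "rescued"
FILTER_VOCABULARY = (
    FILTER_PASS,
    FILTER_OXIDATION,
    FILTER_LOW_CONFIDENCE,
    FILTER_INDEL_LOW_VAF,
    FILTER_POPULATION,
    FILTER_RECURRENT,
    FILTER_RESCUED,
)

# VAF rounding tolerance when checking a stored VAF against AD/DP.
VAF_TOLERANCE = 0.005


class CallerRole(str, enum.Enum):
    """Which emulated caller produced a call.

    ``PRIMARY_SNV`` plays the part of the tumor/normal SNV caller whose
    output is curated (MuTect-style); ``SECONDARY_RAW`` is the unfiltered
    single-sample caller used only for the recurrent-artifact and rescue
    rules (Pisces-style); ``INDEL`` is the dedicated small-indel caller
    (Strelka-style).
    """

    PRIMARY_SNV = "primary_snv"
    SECONDARY_RAW = "secondary_raw"
    INDEL = "indel"


@dataclass(frozen=True, order=True)
class GenomicVariant:
    """A single variant identified by (chrom, pos, ref, alt).

    Two calls describe *the same mutation* iff their keys compare equal —
    the same genomic position with the same nucleotide change. Equality,
    hashing and ordering all derive from the four fields.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or any(b not in BASES for b in allele):
                raise ValueError(f"{name} allele {allele!r} must be non-empty A/C/G/T")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_mnv(self) -> bool:
        return len(self.ref) == len(self.alt) and len(self.ref) > 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """One variant observed in one sample replicate by one caller."""

    variant: GenomicVariant
    sample_id: str
    replicate_id: str
    caller_role: CallerRole
    alt_depth: int
    total_depth: int
    vaf: float
    consequence: str = ""
    gene: str = ""
    is_protein_altering: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, total_depth={self.total_depth}]"
            )
        if self.total_depth > 0:
            expected = self.alt_depth / self.total_depth
            if abs(self.vaf - expected) > VAF_TOLERANCE:
                raise ValueError(
                    f"vaf {self.vaf:.4f} disagrees with AD/DP ({expected:.4f}) "
                    f"beyond tolerance {VAF_TOLERANCE}"
                )
        is_indel_role = self.caller_role == CallerRole.INDEL
        if is_indel_role != self.variant.is_indel:
            raise ValueError(
                f"caller_role={self.caller_role.value} inconsistent with alleles "
                f"{self.variant.ref}>{self.variant.alt}"
            )

    @property
    def key(self) -> GenomicVariant:
        return self.variant

    def with_role(self, role: CallerRole) -> "VariantCall":
        return replace(self, caller_role=role)


@dataclass
class SampleMeta:
    """Manifest entry for one sequenced tumor (or normal) sample.

    Concurrent cardiac and splenic samples sharing a ``patient_id`` form a
    paired lesion; downstream case collapsing merges them into one case.
    """

    sample_id: str
    patient_id: str
    species: str
    tissue: str
    cohort: str
    extraction_kit: str = ""
    replicate_ids: list[str] = field(default_factory=list)

    SPECIES = ("canine", "feline")
    TISSUES = ("cardiac", "splenic", "skin")
    COHORTS = ("canine_visceral", "canine_skin", "feline_skin")

    def __post_init__(self) -> None:
        if self.species not in self.SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.tissue not in self.TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.cohort not in self.COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")


@dataclass
class FilterConfig:
    """Thresholds for the somatic-variant filtering cascade.

    Defaults are the published values: C>A/G>T oxidation artifacts at
    VAF <= 0.10 in deamination-prone contexts; high-confidence C>T calls
    need >= 10 supporting reads and VAF > 0.05 (strict, reflecting the
    cytosine-deamination artifact mode), other SNVs >= 8 reads and
    VAF >= 0.04 (inclusive); indels below VAF 0.10 are discarded; variants
    at >= 1% population allele frequency are treated as germline leakage;
    a call is a recurrent artifact when the raw secondary caller sees it in
    >= 10% of samples where the primary made no call, with VAFs homogeneous
    around 0.05.
    """

    oxidation_vaf_max: float = 0.10
    ct_min_alt_reads: int = 10
    ct_min_vaf_exclusive: float = 0.05
    other_min_alt_reads: int = 8
    other_min_vaf_inclusive: float = 0.04
    indel_min_vaf: float = 0.10
    population_af_max: float = 0.01
    recurrent_sample_fraction: float = 0.10
    recurrent_vaf_split: float = 0.05
    min_base_quality: int = 30
    # Interpretation toggles (see docs/methods.md):
    # treat the C>T high-confidence rule strand-symmetrically (C>T or G>A)?
    ct_strand_symmetric: bool = True
    # recurrent-artifact denominator: samples without a primary call at the
    # key ("primary_negative", literal reading) or the whole cohort.
    recurrent_denominator: str = "primary_negative"
    # require the secondary VAFs to be homogeneous (all < split or all >= split)?
    recurrent_homogeneity_required: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.oxidation_vaf_max <= 1:
            raise ValueError("oxidation_vaf_max outside (0, 1]")
        if self.ct_min_alt_reads < 0 or self.other_min_alt_reads < 0:
            raise ValueError("read-count thresholds must be non-negative")
        for name in ("ct_min_vaf_exclusive", "other_min_vaf_inclusive",
                     "indel_min_vaf", "population_af_max",
                     "recurrent_sample_fraction", "recurrent_vaf_split"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.recurrent_denominator not in ("primary_negative", "all_samples"):
            raise ValueError(f"unknown recurrent_denominator {self.recurrent_denominator!r}")


class PopulationFrequencyTable:
    """Allele frequencies in a reference population panel.

    Emulates the role of the 722-genome canine (or 54-genome feline) panel:
    variants common in the panel are germline polymorphisms, not somatic
    events. Absent keys have frequency 0.
    """

    def __init__(self, frequencies: dict[GenomicVariant, float] | None = None):
        self._af: dict[GenomicVariant, float] = {}
        for key, af in (frequencies or {}).items():
            self[key] = af

    def __setitem__(self, key: GenomicVariant, af: float) -> None:
        if not 0 <= af <= 1:
            raise ValueError(f"allele frequency {af} outside [0, 1]")
        self._af[key] = af

    def af(self, key: GenomicVariant) -> float:
        return self._af.get(key, 0.0)

    def __contains__(self, key: GenomicVariant) -> bool:
        return key in self._af

    def __len__(self) -> int:
        return len(self._af)

    def positions(self) -> set[tuple[str, int]]:
        """(chrom, pos) sites present in the panel (polymorphic sites)."""
        return {(k.chrom, k.pos) for k in self._af}

    def items(self):
        return self._af.items()

    @classmethod
    def from_tsv(cls, path) -> "PopulationFrequencyTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        table = cls()
        for row in df.itertuples(index=False):
            table[GenomicVariant(row.chrom, int(row.pos), row.ref, row.alt)] = float(row.af)
        return table

    def to_tsv(self, path) -> None:
        rows = sorted(self._af.items(), key=lambda kv: kv[0])
        pd.DataFrame(
            [(k.chrom, k.pos, k.ref, k.alt, af) for k, af in rows],
            columns=["chrom", "pos", "ref", "alt", "af"],
        ).to_csv(path, sep="\t", index=False)


def load_manifest(path) -> list[SampleMeta]:
    """Read a sample manifest TSV (one row per sample replicate).

    Columns: sample_id, patient_id, species, tissue, cohort,
    extraction_kit, replicate_id. Rows with the same sample_id are merged
    into one :class:`SampleMeta` whose ``replicate_ids`` lists every
    replicate in file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "species", "tissue", "cohort",
                "extraction_kit", "replicate_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    samples: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        meta = samples.get(row.sample_id)
        if meta is None:
            meta = SampleMeta(
                sample_id=row.sample_id,
                patient_id=row.patient_id,
                species=row.species,
                tissue=row.tissue,
                cohort=row.cohort,
                extraction_kit=row.extraction_kit,
            )
            samples[row.sample_id] = meta
        if row.replicate_id not in meta.replicate_ids:
            meta.replicate_ids.append(row.replicate_id)
    return list(samples.values())


def write_manifest(samples: list[SampleMeta], path) -> None:
    rows = [
        (s.sample_id, s.patient_id, s.species, s.tissue, s.cohort,
         s.extraction_kit, rep)
        for s in samples
        for rep in s.replicate_ids
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "species", "tissue", "cohort",
                 "extraction_kit", "replicate_id"],
    ).to_csv(path, sep="\t", index=False)
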