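"""96-channel mutation spectra, signature extraction and cosine matching.

Spectra are pyrimidine-centered: a substitution whose reference base is a
purine is reverse-complemented into one of the six pyrimidine classes
(C>A, C>G, C>T, T>A, T>C, T>G) with its trinucleotide context, giving the
standard 96 channels in COSMIC order. Signature extraction is
non-negative matrix factorization of the samples x 96 count matrix,
restricted to mutation-rich samples (> 100 mutations); extracted and
per-sample profiles are compared to a catalog by cosine similarity.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .io import reverse_complement, trinucleotide_context
from .model import BASES, VariantCall

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "SUBSTITUTIONS",
    "SignatureCatalog",
    "SignatureExtraction",
    "SignatureMatch",
    "TrinucleotideSpectrum",
    "build_spectrum",
    "channel_index",
    "classify_uv_samples",
    "cosine_similarity",
    "extract_signatures",
    "load_synthetic_catalog",
    "match_catalog",
    "synthetic_signature_catalog",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: channel labels in COSMIC order, e.g. "A[C>A]A", "A[C>A]C", ...
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def channel_index(ref: str, alt: str, context: str) -> int:
    """Map one SNV plus its reference 3-mer context to a channel index.

    Purine-reference substitutions are folded onto the opposite strand.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on {ref!r}")
    if ref in "AG":
        ref, alt = reverse_complement(ref), reverse_complement(alt)
        context = reverse_complement(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return _CHANNEL_INDEX[label]


@dataclass
class TrinucleotideSpectrum:
    """96-channel mutation count vector for one sample."""

    sample_id: str
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(96, dtype=np.int64))
    n_skipped: int = 0

    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name=self.sample_id)


def build_spectrum(calls: list[VariantCall], reference: Fasta,
                   sample_id: str | None = None) -> TrinucleotideSpectrum:
    """Count each SNV into exactly one of the 96 channels.

    Non-SNVs (indels, multi-nucleotide substitutions) and SNVs whose
    context is unavailable at a contig edge are skipped; the skip count
    is recorded and logged.
    """
    if sample_id is None:
        sample_id = calls[0].sample_id if calls else ""
    spectrum = TrinucleotideSpectrum(sample_id=sample_id)
    for call in calls:
        v = call.variant
        if not v.is_snv:
            spectrum.n_skipped += 1
            continue
        context = trinucleotide_context(reference, v.chrom, v.pos)
        if context is None:
            spectrum.n_skipped += 1
            continue
        spectrum.counts[channel_index(v.ref, v.alt, context)] += 1
    if spectrum.n_skipped:
        logger.info("spectrum %s: skipped %d non-SNV/edge calls",
                    sample_id, spectrum.n_skipped)
    return spectrum


class SignatureCatalog:
    """A named set of 96-channel signature profiles, each summing to 1."""

    def __init__(self, profiles: pd.DataFrame):
        # rows: 96 channels in COSMIC order; columns: signature names
        if list(profiles.index) != list(CHANNELS):
            profiles = profiles.reindex(list(CHANNELS))
        if profiles.isna().any().any():
            raise ValueError("catalog is missing channels")
        if (profiles.values < 0).any():
            raise ValueError("catalog profiles must be non-negative")
        sums = profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"catalog columns must sum to 1, got {dict(sums)}")
        self.profiles = profiles

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    def vector(self, name: str) -> np.ndarray:
        return self.profiles[name].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        """Read the standard 96-row layout (Type, Subtype, one column per
        signature); Subtype is the trinucleotide, Type the substitution."""
        df = pd.read_csv(path, sep="\t")
        if not {"Type", "Subtype"} <= set(df.columns):
            raise ValueError("catalog TSV needs Type and Subtype columns")
        labels = [f"{sub[0]}[{typ}]{sub[2]}"
                  for typ, sub in zip(df["Type"], df["Subtype"])]
        profiles = df.drop(columns=["Type", "Subtype"])
        profiles.index = labels
        return cls(profiles)

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({
            "Type": [c[2:5] for c in CHANNELS],
            "Subtype": [c[0] + c[3] + c[6] for c in CHANNELS],
        })
        for name in self.names:
            out[name] = self.profiles[name].to_numpy()
        out.to_csv(path, sep="\t", index=False)


def synthetic_signature_catalog() -> SignatureCatalog:
    """A small synthetic 4-signature catalog for tests and examples.

    The profiles are *stand-ins* built from the qualitative shapes of the
    UV signatures (SBS7a/SBS7b: C>T at dipyrimidines, with 5'-T and 5'-C
    emphasis respectively) and the sequencing-artifact signatures
    (SBS45: C>A; SBS52: mixed C>A / T>C). They are not the COSMIC
    profiles and carry the same names only so that code paths expecting
    those identifiers can be exercised without redistribution.
    """
    profiles = pd.DataFrame(0.0, index=list(CHANNELS),
                            columns=["SBS7a", "SBS7b", "SBS45", "SBS52"])
    three_weights = {"A": 0.2, "C": 0.3, "G": 0.1, "T": 0.4}
    for three, w in three_weights.items():
        profiles.loc[f"T[C>T]{three}", "SBS7a"] = w
        profiles.loc[f"C[C>T]{three}", "SBS7b"] = w
    for five in BASES:
        for three, w in three_weights.items():
            profiles.loc[f"{five}[C>A]{three}", "SBS45"] = w / 4.0
    for five in BASES:
        for three in BASES:
            profiles.loc[f"{five}[C>A]{three}", "SBS52"] += 0.5 / 16
            profiles.loc[f"{five}[T>C]{three}", "SBS52"] += 0.5 / 16
    return SignatureCatalog(profiles)


def load_synthetic_catalog() -> SignatureCatalog:
    """Load the packaged synthetic catalog TSV."""
    ref = importlib.resources.files("ffpesoma") / "data" / "synthetic_sbs_catalog.tsv"
    with importlib.resources.as_file(ref) as path:
        return SignatureCatalog.from_tsv(path)


def cosine_similarity(u, v) -> float:
    """Cosine of the angle between two non-negative spectra, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class SignatureMatch:
    query_id: str
    best_name: str
    cosine: float
    table: pd.Series  # cosine to every catalog signature


def match_catalog(vector, catalog: SignatureCatalog,
                  query_id: str = "") -> SignatureMatch:
    sims = pd.Series(
        {name: cosine_similarity(vector, catalog.vector(name))
         for name in catalog.names})
    best = sims.idxmax()
    return SignatureMatch(query_id=query_id, best_name=best,
                          cosine=float(sims[best]), table=sims)


@dataclass
class SignatureExtraction:
    """Result of NMF signature extraction over mutation-rich samples."""

    signatures: pd.DataFrame  # n_signatures x 96, rows sum to 1
    exposures: pd.DataFrame  # samples x n_signatures
    reconstruction_error: float
    sample_ids: list[str]

    @property
    def empty(self) -> bool:
        return self.signatures.shape[0] == 0


def extract_signatures(spectra: list[TrinucleotideSpectrum],
                       n_signatures: int, seed: int,
                       min_mutations: int = 100,
                       n_restarts: int = 10) -> SignatureExtraction:
    """Extract signatures by multi-restart NMF (Frobenius objective).

    Only samples with more than ``min_mutations`` mutations enter the
    factorization. The multiplicative-update solver is run from
    ``n_restarts`` random initializations and the factorization with the
    lowest reconstruction error is kept; rows of the signature matrix
    are normalized to sum to 1, with exposures rescaled to compensate.
    Returns an empty result when no sample passes the gate.
    """
    from sklearn.decomposition import NMF

    if n_signatures < 1:
        raise ValueError("n_signatures must be >= 1")
    eligible = [s for s in spectra if s.total() > min_mutations]
    if not eligible:
        logger.warning("no sample exceeds %d mutations: nothing to extract",
                       min_mutations)
        return SignatureExtraction(
            signatures=pd.DataFrame(columns=list(CHANNELS)),
            exposures=pd.DataFrame(), reconstruction_error=0.0,
            sample_ids=[])
    matrix = np.vstack([s.counts for s in eligible]).astype(float)
    sample_ids = [s.sample_id for s in eligible]

    best = None
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        model = NMF(n_components=n_signatures, init="random", solver="mu",
                    beta_loss="frobenius", max_iter=5000, tol=1e-10,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        exposures = model.fit_transform(matrix)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, exposures, model.components_)
    err, exposures, components = best

    row_sums = components.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    signatures = components / row_sums[:, None]
    exposures = exposures * row_sums[None, :]
    sig_names = [f"S{i + 1}" for i in range(n_signatures)]
    return SignatureExtraction(
        signatures=pd.DataFrame(signatures, index=sig_names,
                                columns=list(CHANNELS)),
        exposures=pd.DataFrame(exposures, index=sample_ids,
                               columns=sig_names),
        reconstruction_error=float(err),
        sample_ids=sample_ids,
    )


def classify_uv_samples(spectra: list[TrinucleotideSpectrum],
                        catalog: SignatureCatalog,
                        min_mutations: int = 100,
                        cosine_threshold: float = 0.80,
                        extraction: SignatureExtraction | None = None,
                        ) -> dict[str, bool]:
    """Flag samples bearing a UV mutational signature.

    A sample is UV-flagged when it is mutation-rich (more than
    ``min_mutations`` mutations, the same gate used for extraction) AND
    its spectrum — or, if provided, any extracted signature it is exposed
    to — has cosine similarity >= ``cosine_threshold`` to SBS7a or SBS7b.
    """
    for required in ("SBS7a", "SBS7b"):
        if required not in catalog.names:
            raise ValueError(f"catalog lacks {required}")
    uv_vectors = [catalog.vector("SBS7a"), catalog.vector("SBS7b")]

    extracted_uv_cosines: dict[str, float] = {}
    if extraction is not None and not extraction.empty:
        sig_cos = {
            name: max(cosine_similarity(row.to_numpy(), v)
                      for v in uv_vectors)
            for name, row in extraction.signatures.iterrows()}
        for sample_id in extraction.exposures.index:
            weights = extraction.exposures.loc[sample_id]
            dominant = weights.idxmax()
            extracted_uv_cosines[sample_id] = sig_cos[dominant]

    flags: dict[str, bool] = {}
    for spectrum in spectra:
        if spectrum.total() <= min_mutations:
            flags[spectrum.sample_id] = False
            continue
        cos = max(cosine_similarity(spectrum.counts, v) for v in uv_vectors)
        cos = max(cos, extracted_uv_cosines.get(spectrum.sample_id, 0.0))
        flags[spectrum.sample_id] = cos >= cosine_threshold
    return flags
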