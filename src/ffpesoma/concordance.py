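"""Paired-tumor clonality analysis via shared somatic mutations.

Concurrent lesions (e.g. cardiac and splenic tumors in one patient) are
clonally related — one a metastasis of the other — when they share
somatic mutations, defined strictly as the same genomic position with
the same nucleotide change. Cross-patient comparisons provide the
contrast: true somatic mutations are almost always private to a patient.
A permutation test formalizes this by re-pairing one tumor with random
other patients' tumors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenomicVariant

__all__ = [
    "PairOverlap",
    "cross_patient_uniqueness",
    "permutation_sharing_test",
    "shared_mutations",
]


@dataclass
class PairOverlap:
    patient_id: str
    sample_a: str
    sample_b: str
    n_unique_a: int
    n_unique_b: int
    n_shared: int
    shared_keys: list[GenomicVariant]


def shared_mutations(keys_a: set[GenomicVariant], keys_b: set[GenomicVariant],
                     sample_a: str, sample_b: str,
                     patient_id: str = "") -> PairOverlap:
    """Intersect two final per-sample call sets by variant key."""
    if sample_a == sample_b:
        raise ValueError(f"same sample supplied twice: {sample_a}")
    shared = keys_a & keys_b
    return PairOverlap(
        patient_id=patient_id, sample_a=sample_a, sample_b=sample_b,
        n_unique_a=len(keys_a - shared), n_unique_b=len(keys_b - shared),
        n_shared=len(shared), shared_keys=sorted(shared))


def cross_patient_uniqueness(
        keys_by_sample: dict[str, set[GenomicVariant]],
        patient_of: dict[str, str],
        pair_shared_keys: dict[str, list[GenomicVariant]],
        ) -> tuple[pd.DataFrame, float]:
    """How private are pair-shared mutations to their patient?

    For every key shared within a concurrent pair, count the number of
    *other* patients whose final call sets carry the same key. Returns
    the per-key table and the fraction of pair-shared keys private to
    their patient (other-patient count 0).
    """
    patients = set(patient_of.values())
    if len(patients) < 2:
        raise ValueError("need at least 2 patients")
    carriers: dict[GenomicVariant, set[str]] = {}
    for sample_id, keys in keys_by_sample.items():
        for key in keys:
            carriers.setdefault(key, set()).add(patient_of[sample_id])
    rows = []
    for patient_id, shared in pair_shared_keys.items():
        for key in shared:
            n_other = len(carriers.get(key, set()) - {patient_id})
            rows.append((patient_id, str(key), n_other))
    table = pd.DataFrame(rows, columns=["patient_id", "variant",
                                        "n_other_patients"])
    private_fraction = (float((table["n_other_patients"] == 0).mean())
                        if len(table) else float("nan"))
    return table, private_fraction


def permutation_sharing_test(
        keys_a: set[GenomicVariant],
        keys_b: set[GenomicVariant],
        sample_a: str, sample_b: str,
        keys_by_sample: dict[str, set[GenomicVariant]],
        patient_of: dict[str, str],
        n_permutations: int = 999,
        seed: int = 0) -> tuple[int, float]:
    """Empirical p-value for the observed shared-mutation count.

    The null re-pairs tumor A with a tumor drawn from a random *other*
    patient and records the shared count; with add-one smoothing
    p = (1 + #{null >= observed}) / (1 + n_permutations), so p is always
    in (0, 1].
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    patient_a = patient_of[sample_a]
    pool = [sid for sid in keys_by_sample
            if patient_of[sid] not in (patient_a, patient_of[sample_b])]
    if len({patient_of[sid] for sid in pool}) < 1 or len(set(patient_of.values())) < 3:
        raise ValueError("cohort too small for re-pairing (need >= 3 patients)")
    observed = len(keys_a & keys_b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        partner = pool[rng.integers(len(pool))]
        if len(keys_a & keys_by_sample[partner]) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return observed, p
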