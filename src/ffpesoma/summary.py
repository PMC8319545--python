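"""Cohort-level summaries: case collapsing, driver-gene recurrence,
oncoprint matrices, cross-species overlap and the germline risk screen.

A *case* is a patient: concurrent cardiac and splenic tumors collapse to
one case (a mutation counts if present in either lesion or both), and a
gene counts once per case regardless of how many of its mutations a case
carries. Recurrence is reported over protein-altering mutations by
default, optionally excluding UV-signature cases from both numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import GenomicVariant, SampleMeta, VariantCall

__all__ = [
    "CaseCallSet",
    "collapse_cases",
    "cross_species_overlap",
    "gene_recurrence",
    "germline_risk_screen",
    "multi_hit_cases",
    "render_oncoprint",
    "RISK_GENES",
]

#: human angiosarcoma susceptibility genes screened in the germline
#: (the panel excludes POLH and PTHR1, which were not in the bait design)
RISK_GENES = ("ERCC2", "IDH1", "IDH2", "PIK3CA", "POT1", "PTEN", "RB1",
              "TP53", "XPC")

# consequence severity for annotation-conflict resolution (higher wins)
_SEVERITY = {"synonymous": 0, "": 0, "splice_region": 1, "missense": 2,
             "inframe": 3, "nonsense": 4, "frameshift": 5}


def _severity(consequence: str) -> int:
    return _SEVERITY.get(consequence, 1)


def normalize_symbol(gene: str) -> str:
    """Case-insensitive gene-symbol comparison with species-prefix
    stripping (e.g. 'cfTP53' / 'Tp53' / 'TP53' all compare equal)."""
    g = gene.strip()
    for prefix in ("cf", "fc"):
        if g.lower().startswith(prefix) and len(g) > len(prefix) and g[len(prefix)].isupper():
            g = g[len(prefix):]
    return g.upper()


@dataclass
class CaseCallSet:
    """Merged mutation set for one case (patient)."""

    patient_id: str
    cohort: str
    calls: dict[GenomicVariant, VariantCall] = field(default_factory=dict)

    def genes(self, protein_altering_only: bool = True) -> set[str]:
        return {normalize_symbol(c.gene) for c in self.calls.values()
                if c.gene and (c.is_protein_altering or not protein_altering_only)}


def collapse_cases(manifest: list[SampleMeta],
                   final_calls: dict[str, dict[GenomicVariant, VariantCall]],
                   ) -> list[CaseCallSet]:
    """Collapse per-sample call sets into one case per patient.

    Concurrent lesions merge by key union; when both lesions carry the
    same key with different annotations the most severe consequence is
    kept. Patients with no samples in ``final_calls`` are an error.
    """
    by_patient: dict[str, CaseCallSet] = {}
    seen_patients: dict[str, int] = {}
    for sample in manifest:
        if sample.sample_id not in final_calls:
            continue
        case = by_patient.setdefault(
            sample.patient_id,
            CaseCallSet(patient_id=sample.patient_id, cohort=sample.cohort))
        seen_patients[sample.patient_id] = seen_patients.get(sample.patient_id, 0) + 1
        for key, call in final_calls[sample.sample_id].items():
            existing = case.calls.get(key)
            if existing is None or _severity(call.consequence) > _severity(existing.consequence):
                case.calls[key] = call
    missing = {s.patient_id for s in manifest} - set(seen_patients)
    if missing:
        raise ValueError(f"patients with zero samples: {sorted(missing)}")
    return list(by_patient.values())


def gene_recurrence(cases: list[CaseCallSet],
                    protein_altering_only: bool = True,
                    exclude_uv: bool = False,
                    uv_flags: dict[str, bool] | None = None) -> pd.DataFrame:
    """Per-(cohort, gene) counts of cases with >= 1 qualifying mutation.

    With ``exclude_uv`` the UV-flagged cases leave both numerator and
    denominator (``uv_flags`` maps patient_id to flag).
    """
    uv_flags = uv_flags or {}
    if exclude_uv:
        cases = [c for c in cases if not uv_flags.get(c.patient_id, False)]
    totals: dict[str, int] = {}
    counts: dict[tuple[str, str], int] = {}
    for case in cases:
        totals[case.cohort] = totals.get(case.cohort, 0) + 1
        for gene in case.genes(protein_altering_only):
            counts[(case.cohort, gene)] = counts.get((case.cohort, gene), 0) + 1
    rows = [(cohort, gene, n, totals[cohort], n / totals[cohort])
            for (cohort, gene), n in counts.items()]
    df = pd.DataFrame(rows, columns=["cohort", "gene", "n_cases_mutated",
                                     "n_cases_total", "fraction"])
    return df.sort_values(["cohort", "n_cases_mutated", "gene"],
                          ascending=[True, False, True]).reset_index(drop=True)


def multi_hit_cases(cases: list[CaseCallSet], gene: str,
                    protein_altering_only: bool = True) -> int:
    """Number of cases carrying >= 2 *distinct* mutations in ``gene``.

    The same key present in both lesions of a pair is one distinct
    mutation, not two.
    """
    target = normalize_symbol(gene)
    count = 0
    for case in cases:
        keys = {key for key, call in case.calls.items()
                if normalize_symbol(call.gene) == target
                and (call.is_protein_altering or not protein_altering_only)}
        if len(keys) >= 2:
            count += 1
    return count


def cross_species_overlap(recurrence: pd.DataFrame,
                          human_genes: pd.DataFrame,
                          min_species: int = 2) -> pd.DataFrame:
    """Genes mutated in at least ``min_species`` of the three species.

    ``recurrence`` is a gene_recurrence table over the canine/feline
    cohorts; ``human_genes`` is a TSV-derived frame with columns
    ``gene`` and ``fraction`` (e.g. an Angiosarcoma Project export).
    Canine cohorts (visceral + skin) count as one species. Output is an
    oncoprint-style matrix of per-species mutated fractions.
    """
    if human_genes.empty:
        raise ValueError("empty human gene list")
    species_of = {"canine_visceral": "canine", "canine_skin": "canine",
                  "feline_skin": "feline"}
    fractions: dict[str, dict[str, float]] = {}
    for row in recurrence.itertuples(index=False):
        species = species_of.get(row.cohort, row.cohort)
        gene = normalize_symbol(row.gene)
        fractions.setdefault(gene, {})
        fractions[gene][species] = max(fractions[gene].get(species, 0.0),
                                       row.fraction)
    for row in human_genes.itertuples(index=False):
        gene = normalize_symbol(row.gene)
        fractions.setdefault(gene, {})
        fractions[gene]["human"] = float(row.fraction)
    rows = []
    for gene, by_species in sorted(fractions.items()):
        if len(by_species) >= min_species:
            rows.append((gene,
                         by_species.get("canine", 0.0),
                         by_species.get("feline", 0.0),
                         by_species.get("human", 0.0),
                         len(by_species)))
    return pd.DataFrame(rows, columns=["gene", "canine_fraction",
                                       "feline_fraction", "human_fraction",
                                       "n_species"])


def germline_risk_screen(germline_calls: dict[str, list[VariantCall]],
                         risk_genes: tuple[str, ...] = RISK_GENES,
                         liftover_available: bool = False) -> pd.DataFrame:
    """Protein-altering germline variants in the risk-gene orthologs.

    ``germline_calls`` maps patient to the germline-mode caller output.
    Without a configured reference-liftover check every retained variant
    carries a reference-error caution flag.
    """
    if not risk_genes:
        raise ValueError("empty risk gene list")
    wanted = {normalize_symbol(g) for g in risk_genes}
    rows = []
    for patient_id, calls in germline_calls.items():
        for call in calls:
            if not call.is_protein_altering:
                continue
            if normalize_symbol(call.gene) not in wanted:
                continue
            rows.append((patient_id, normalize_symbol(call.gene),
                         str(call.variant), call.consequence, call.vaf,
                         not liftover_available))
    return pd.DataFrame(rows, columns=["patient_id", "gene", "variant",
                                       "consequence", "vaf",
                                       "reference_error_caution"])


def render_oncoprint(cases: list[CaseCallSet],
                     protein_altering_only: bool = True,
                     out_tsv=None, out_plot=None) -> pd.DataFrame:
    """Genes x cases matrix of consequence categories.

    Rows are ordered by descending recurrence then alphabetically; cell
    values are the most severe consequence the case carries in the gene
    (empty = unmutated). Optionally writes a TSV and a simple plot.
    """
    case_ids = [c.patient_id for c in cases]
    gene_hits: dict[str, dict[str, str]] = {}
    for case in cases:
        for key, call in case.calls.items():
            if protein_altering_only and not call.is_protein_altering:
                continue
            if not call.gene:
                continue
            gene = normalize_symbol(call.gene)
            row = gene_hits.setdefault(gene, {})
            prev = row.get(case.patient_id, "")
            if prev == "" or _severity(call.consequence) > _severity(prev):
                row[case.patient_id] = call.consequence
    order = sorted(gene_hits,
                   key=lambda g: (-len(gene_hits[g]), g))
    matrix = pd.DataFrame(
        [[gene_hits[g].get(cid, "") for cid in case_ids] for g in order],
        index=order, columns=case_ids)
    matrix.index.name = "gene"
    if out_tsv is not None:
        matrix.to_csv(out_tsv, sep="\t")
    if out_plot is not None:
        _plot_oncoprint(matrix, out_plot)
    return matrix


def _plot_oncoprint(matrix: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    consequences = sorted({v for row in matrix.values for v in row if v},
                          key=_severity)
    code = {c: i + 1 for i, c in enumerate(consequences)}
    grid = matrix.map(lambda v: code.get(v, 0)) if hasattr(matrix, "map") \
        else matrix.applymap(lambda v: code.get(v, 0))
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.shape[1]), max(3, 0.3 * matrix.shape[0])))
    ax.imshow(grid.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90,
                  fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
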