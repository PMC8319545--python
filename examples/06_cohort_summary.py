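"""Case collapsing, driver-gene recurrence and the germline risk screen.

Concurrent lesions of one patient collapse to a single case; a gene
counts once per case when it carries at least one protein-altering
mutation. The oncoprint matrix and the cross-species overlap follow,
plus the screen for germline variants in angiosarcoma risk genes.
"""

import tempfile

import pandas as pd

from ffpesoma import open_reference, run_filter_cascade
from ffpesoma.summary import (
    collapse_cases,
    cross_species_overlap,
    gene_recurrence,
    germline_risk_screen,
    multi_hit_cases,
    render_oncoprint,
)
from ffpesoma.synthetic import GeneratorConfig, generate_cohort, generate_reference

with tempfile.TemporaryDirectory() as workdir:
    config = GeneratorConfig(seed=31, n_canine_skin_patients=4,
                             n_feline_skin_patients=4, n_uv_samples=0)
    ref_path = f"{workdir}/reference.fa"
    generate_reference(config, ref_path)
    synthetic = generate_cohort(config, ref_path)
    result = run_filter_cascade(synthetic.cohort, open_reference(ref_path),
                                synthetic.population)

    cases = collapse_cases(synthetic.cohort.samples, result.final)
    print(f"{len(synthetic.cohort.samples)} samples collapse to "
          f"{len(cases)} cases (concurrent pairs merge)\n")

    table = gene_recurrence(cases)
    visceral = table[table["cohort"] == "canine_visceral"].head(5)
    print("top recurrently mutated genes, canine visceral cohort:")
    for row in visceral.itertuples(index=False):
        print(f"  {row.gene:10s} {row.n_cases_mutated}/{row.n_cases_total} "
              f"cases ({100 * row.fraction:.0f}%)")
    top_gene = visceral.iloc[0].gene
    print(f"cases with two or more distinct {top_gene} mutations: "
          f"{multi_hit_cases(cases, top_gene)}")

    matrix = render_oncoprint(cases)
    print(f"\noncoprint matrix: {matrix.shape[0]} genes x "
          f"{matrix.shape[1]} cases (rows by descending recurrence)")

    human = pd.DataFrame({"gene": visceral["gene"].head(3),
                          "fraction": [0.21, 0.10, 0.06]})
    overlap = cross_species_overlap(table, human)
    print(f"genes mutated in >= 2 of the 3 species: "
          f"{', '.join(overlap['gene'])}")

    screen = germline_risk_screen(synthetic.germline_calls)
    print(f"\ngermline risk screen: {len(screen)} protein-altering "
          f"variants across {screen['gene'].nunique()} risk genes "
          f"({', '.join(sorted(screen['gene'].unique()))})")
    print("Every retained germline variant carries a reference-error "
          "caution flag until a liftover check is configured.")
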