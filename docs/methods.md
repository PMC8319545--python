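# Methods

This note documents the models, rules and design choices behind
`ffpesoma`: what each stage computes, the parameters that matter, what
the synthetic cohorts do and do not emulate, and the numerical details
a user would otherwise have to read out of the source.

## The filtering cascade

### Artifact physics and the rules that target it

FFPE fixation deaminates cytosine to uracil, which sequences as C>T
(G>A on the other strand) at low variant allele fraction (VAF).
Oxidative damage converts guanine to 8-oxoguanine, which pairs with
adenine and sequences as C>A (G>T) — preferentially where the pyrimidine
strand reads CCN or TCN. Because both damage modes hit individual DNA
molecules rather than cells, their VAFs are low and, crucially,
*independent between extraction replicates* of the same core pair,
whereas a real somatic mutation appears in both replicates at a
correlated VAF. The cascade exploits exactly this:

| stage | rule | parameters (defaults) |
|---|---|---|
| 1 | population | remove keys at panel AF ≥ `population_af_max` = 0.01 |
| 2 | oxidation | C>A, VAF ≤ `oxidation_vaf_max` = 0.10, context CC\*/TC\*; mirrored G>T at \*GG/\*GA |
| 3 | high confidence + consensus | C>T: alt reads ≥ 10 AND VAF > 0.05 (strict); other substitutions: alt reads ≥ 8 AND VAF ≥ 0.04 (inclusive); a sub-threshold call survives iff the same key is high-confidence in another replicate |
| 4 | indel VAF | keep iff VAF ≥ `indel_min_vaf` = 0.10 (strict `<` discards) |
| 5 | recurrent artifact | key in the raw secondary calls of ≥ `recurrent_sample_fraction` = 10% of primary-negative samples, with homogeneous VAFs around `recurrent_vaf_split` = 0.05 |
| 6 | rescue | key high-confidence in replicate A, absent from replicate B's primary calls, present in B's raw secondary calls → restored in B |

The boundary conventions are deliberate and asymmetric: the C>T VAF bar
is *strict* (`> 0.05`) because deamination concentrates exactly at low
VAF, while the other-substitution bar is *inclusive* (`≥ 0.04`).
"Supporting reads" means alt-allele read count, not total depth. The
final per-sample call set is the union over replicates of passing and
rescued calls, collapsed by variant key (chrom, pos, ref, alt); two
calls are the same mutation iff their keys are equal.

### Interpretation choices (configurable)

Three points are under-determined by the rule statements and are
resolved as explicit `FilterConfig` toggles:

* **`ct_strand_symmetric` (default True)** — the C>T high-confidence
  rule also covers G>A. Deamination is strand-symmetric (the artifact
  appears as G>A whenever the read maps to the opposite strand), and the
  oxidation rule's explicit reverse-complement clause shows the same
  convention; a literal C>T-only reading is available.
* **`recurrent_denominator` (default `"primary_negative"`)** — the 10%
  fraction is taken over samples in which the primary caller made no
  call at the key (the literal reading); `"all_samples"` uses the whole
  cohort.
* **`recurrent_homogeneity_required` (default True)** — the VAF
  parenthetical is read as a homogeneity requirement: mixed strata
  (some secondary VAFs below 0.05, some at/above) mean the signal is not
  a consistent systematic artifact and the call is kept. The alternative
  reading — either stratum independently sufficient — is implemented
  behind the toggle and tested.

Replicate consensus evaluates the vouching call on replicates that are
themselves alive after the key-level stages (a population- or
oxidation-failed call cannot vouch). Rescue can only restore keys that
survived in the vouching replicate, so it never resurrects a
population, oxidation or recurrent failure. Multi-nucleotide
substitutions (equal-length ref/alt > 1) bypass the oxidation filter and
the 96-channel spectrum, use the "other substitution" high-confidence
thresholds, and participate in all key-based logic. Base quality ≥ 30 is
a property of the emulated callers' input and is not re-checked per
read.

Stages 1, 2 and 4 depend only on the single call plus static tables, so
they commute; the implemented order (population → oxidation →
confidence/consensus → indel → recurrent → rescue) fixes which rule is
*reported* when several would fire.

## Synthetic cohorts

The generator emulates the statistical structure of a duplicate-core
FFPE panel study: 15 visceral patients (14 with concurrent
cardiac+splenic lesions), 13 + 13 skin patients in two species, two
extraction replicates per tumor, and three caller roles (stringent
primary with matched-normal subtraction semantics; permissive secondary
as a superset caller; dedicated indel caller). Sequencing depth is
negative-binomial with mean 300 and size 50, matching ~300-fold median
target coverage; alt counts are binomial in the planted VAF, which is
what makes replicate VAFs correlated for real mutations and independent
for artifacts.

Planted distributions (generator choices, stated as such):

* true somatic VAF ~ Beta(5, 15), mean 0.25 — a clonal tumor at ~50%
  purity; 30 SNVs + 3 indels per tumor, 80% shared within a concurrent
  pair; 2 per tumor are "rescue sites" missing from one replicate's
  primary calls but visible to the secondary caller;
* deamination VAF = 0.01 + 0.05·Beta(1.2, 8) (support (0.01, 0.06)),
  150 per replicate, drawn independently per replicate as C>T or G>A;
* oxidation VAF = 0.01 + 0.07·Beta(1.5, 3) (support (0.01, 0.08)), 80
  per replicate at CCN/TCN centers (or the NGG/NGA mirror). The support
  stays below the 0.10 filter window so that even after binomial
  sequencing noise almost every realized VAF is caught; the rare
  artifact whose realized VAF crosses 0.10 escapes the context rule by
  design and is budgeted under the false-discovery criterion;
* 20 recurrent-artifact sites cohort-wide, each emitted into the
  secondary calls of ~25% of samples at VAF uniform(0.015, 0.045) —
  realized exactly rather than binomially, because the rule's premise is
  a homogeneous low-VAF stratum — and into the primary calls of at most
  one sample;
* 200 population-panel variants (half at AF ≥ 1%), with 3 common ones
  leaking into each tumor's calls at VAF 0.5;
* 40 germline variants per patient in a germline-mode call set for the
  risk screen;
* 3 UV samples in the canine skin cohort with 500 extra mutations drawn
  from the synthetic SBS7a-like profile (placed at genome positions
  whose reference context matches the sampled channel, on either
  strand).

These choices make the published thresholds discriminative *by
design*: essentially all deamination mass sits below the C>T VAF bar and
all oxidation mass inside the context filter's window, while < 1% of
true-somatic mass falls below either bar. Expected leakage was computed
from the distributions before any end-to-end run: ≈ 1 artifact per
~33-call sample, i.e. sensitivity ≈ 0.99 and FDR ≈ 0.02–0.03 under the
default conditions.

What the generator does **not** emulate: mapping ambiguity and indel
realignment, FFPE fragment-size effects, GC-coverage bias, subclonal
structure, caller-specific error models, or real genome sequence
composition (contigs are uniform-random, so trinucleotide frequencies
are flat). Passing tests therefore demonstrate that the rules implement
the stated decision boundaries and separate classes *with the planted
statistics*; they do not certify performance on real FFPE data, where
artifact loads and VAF spectra vary widely.

## Clonality analysis

Shared mutations are strict key matches between final (filtered)
per-sample call sets — a C>T contained within another sample's CC>TT is
not a match. The permutation test re-pairs tumor A with a tumor drawn
uniformly from other patients (excluding both pair members' patients)
and records the shared count; with add-one smoothing
p = (1 + #{null ≥ observed}) / (1 + N), N = 999 by default, so p ∈ (0, 1]
and the smallest attainable p is 1/(1+N). The test formalizes the
qualitative argument that cross-patient sharing of specific somatic
mutations is vanishingly unlikely.

## Mutational signatures

Spectra are 96-vectors in standard COSMIC channel order (six
pyrimidine substitution classes × 16 flanking contexts); purine-
reference SNVs are reverse-complemented into pyrimidine channels.
Extraction runs scikit-learn NMF (multiplicative updates, Frobenius
objective, tol 1e-10, up to 5000 iterations) from 10 random restarts,
keeping the lowest reconstruction error; signature rows are normalized
to sum to 1 with exposures rescaled. Only samples with more than 100
mutations enter the factorization — below that a 96-channel spectrum is
too sparse to support it. UV flagging requires the same >100-mutation
gate AND cosine ≥ 0.80 between the sample spectrum (or its dominant
extracted signature) and SBS7a/SBS7b. The 0.80 cutoff is a repository
choice: high enough that a flat or artifact-dominated spectrum
(cosine to SBS7a ≈ 0.3) never flags, low enough to tolerate the
background mutations diluting a genuine UV sample; it is configurable.

The shipped catalog (`data/synthetic_sbs_catalog.tsv`) is *synthetic*:
four profiles with the qualitative shapes of SBS7a/SBS7b (C>T at
dipyrimidines with 5'-T and 5'-C emphasis), SBS45 (C>A) and SBS52
(mixed C>A / T>C), carrying those names only so code paths expecting
the identifiers can run without redistributing COSMIC data. Any real
catalog in the standard 96-row TSV layout (Type, Subtype, one column
per signature) loads through `SignatureCatalog.from_tsv`.

## Mismatch-rate QC

100,000 aligned reads are subsampled uniformly without replacement
(seeded); a mismatch counts when base quality ≥ 30 and the site is
absent from the population panel (non-polymorphic); the statistic is
mismatches per megabase of aligned sequence. Paired per-sample rates
from two extraction kits are compared with the Wilcoxon signed-rank
test: zero differences dropped, exact null for n ≤ 25, normal
approximation with continuity correction above. All differences zero is
reported as a degenerate result with p = 1 rather than an error.

## Copy number

Off-target reads (outside the padded bait intervals) are counted per
fixed-width bin (0-based half-open, BED convention); the profile is
log2((t_i/T)/(n_i/N)) with zero-coverage bins masked. Segmentation is a
simplified circular binary segmentation: recursively, the arc [i, j)
maximizing |t| between arc mean and complement mean (pooled-SD t-like
statistic) is tested by permutation (default 1000 shuffles, α = 0.01,
seeded, with early stopping once significance is impossible — a pure
speed optimization that cannot change the accept/reject decision);
significant splits recurse, every segment keeps ≥ `min_bins` = 5 bins.

Mode normalization estimates the copy-neutral level as the densest
0.05-wide histogram cell over segment means (cells centered on
multiples of the width, weighted by segment length, ties resolved
toward 0) and subtracts it — the assumption is that most of the genome
is copy-neutral. Calling cutoffs derive from a diploid admixture with
tumor purity p: a single-copy gain moves the expected ratio to
log2(1 + p/2) and a loss to log2(1 − p/2); calls fire at half those
values (`calling_factor` = 0.5) so noisy or subclonal events still
call. The exact purity-to-cutoff mapping is this package's declared
formula — a reasonable stand-in where no canonical mapping exists — and
both the factor and the histogram width are configurable. Penetrance is
the per-bin fraction of samples whose covering segment is called gain
(resp. loss). When replicate profiles exist, the replicate with the
highest purity estimate is used; the naive estimator (2 × median
somatic VAF, clipped to (0.05, 1], ≥ 5 SNVs required) stands in when no
external purity estimate is supplied.

## Cohort summaries

A case is a patient: concurrent lesions merge by key union, keeping the
most severe consequence on annotation conflicts (frameshift > nonsense >
inframe > missense > splice_region > synonymous). "Mutated" means ≥ 1
protein-altering mutation surviving the cascade; synonymous and
non-coding variants are excluded by default. Multi-hit counts require
≥ 2 *distinct* keys in the gene — the same mutation in both lesions of
a pair is one. Gene symbols compare case-insensitively after species-
prefix stripping. UV-flagged cases can be excluded from recurrence, in
which case they leave numerator and denominator together. The
cross-species overlap joins the cohort recurrence tables with an
external human gene→fraction TSV and keeps genes mutated in ≥ 2 of the
three species. The germline risk screen retains protein-altering
variants in the nine angiosarcoma susceptibility genes on the panel
(POLH and PTHR1 are off-panel and excluded); every retained variant
carries a reference-error caution flag unless a genome-liftover check
is configured, since apparent germline hits are frequently reference
assembly errors.

## Degenerate inputs and numerical conventions

* Coordinates are 1-based fully closed (VCF) everywhere except SCNA
  bins (BED); FASTA access converts internally.
* VAF is recomputed from AD/DP on VCF read; a stored VAF field is
  ignored. Stored and derived VAF must agree within 0.005.
* Contig-edge SNVs have no trinucleotide context: the oxidation filter
  treats them as not-applicable (the call proceeds to the other rules)
  and spectrum building skips them with a logged count.
* Cohorts of < 2 samples disable the recurrent-artifact filter with a
  logged warning.
* Cosine similarity on a zero vector is an error, not 0.
* Mode-offset ties resolve toward 0 on the log scale; purity ties in
  replicate selection resolve lexicographically; both are logged.

## Problem sizes

Default end-to-end runs use 55 tumor samples × 2 replicates over a 2 ×
500 kb synthetic genome (~270 candidate calls per replicate), 20-sample
copy-number cohorts at 1 kb bins, and 100,000-read SAM fixtures for the
QC — sizes chosen so the full suite and the acceptance script each
complete in well under a minute while every rule still sees hundreds to
thousands of decisions.
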