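# ffpesoma

Somatic-variant curation and cohort analysis for FFPE tumor/normal
targeted panel sequencing, built for comparative oncogenomics of
vascular sarcomas (canine and feline hemangiosarcoma as models of human
angiosarcoma), and applicable to any duplicate-core FFPE panel design.

DNA from formalin-fixed paraffin-embedded (FFPE) tissue is damaged:
cytosine deamination produces low-VAF C>T artifacts and guanine
oxidation ("OxoG") produces low-VAF C>A artifacts biased toward CCN/TCN
sequence contexts. When each tumor core is sequenced as two extraction
replicates and called with both a stringent tumor/normal caller and a
permissive raw caller, the artifact structure becomes separable from
real somatic mutations. This package implements that curation workflow
and the cohort analyses that sit on top of it.

## What it does

**Filtering cascade** (`ffpesoma.filtering`) — candidate calls pass, in
order:

1. *population filter*: variants at allele frequency ≥ 1% in a reference
   population panel are germline leakage;
2. *oxidation filter*: C>A with VAF ≤ 0.1 in context CCN/TCN (or G>T in
   NGG/NGA) is OxoG damage;
3. *high-confidence thresholds with replicate consensus*: a C>T call is
   high-confidence with ≥ 10 supporting reads and VAF > 0.05; other
   substitutions need ≥ 8 reads and VAF ≥ 0.04; a call below the bar
   survives only if the same mutation is high-confidence in the other
   replicate;
4. *indel filter*: indels with VAF < 0.1 are discarded;
5. *recurrent-artifact filter*: a key found by the raw caller in ≥ 10%
   of samples where the stringent caller was silent, at homogeneous VAFs
   (all < 0.05 or all ≥ 0.05), is a systematic artifact;
6. *rescue*: a high-confidence call present in one replicate and missing
   from the other's stringent output is restored there when the raw
   caller saw it.

**Paired-tumor clonality** (`ffpesoma.concordance`) — shared mutations
(same genomic position, same nucleotide change) between concurrent
lesions of one patient, with a permutation test against re-pairings to
random other patients' tumors.

**Mutational signatures** (`ffpesoma.signatures`) — 96-channel
pyrimidine-centered trinucleotide spectra, multi-restart NMF extraction
over mutation-rich samples (> 100 mutations), cosine matching to a
COSMIC-format catalog, and UV flagging (SBS7a/SBS7b at cosine ≥ 0.80).

**Copy number** (`ffpesoma.scna`) — off-target read binning, log2
tumor/normal ratios, circular binary segmentation with permutation
p-values, mode normalization, purity-adjusted gain/loss cutoffs
(gain at ½·log2(1 + p/2), loss at ½·log2(1 − p/2) for purity p), and
cohort penetrance tracks.

**Cohort summaries** (`ffpesoma.summary`) — case collapsing (concurrent
lesions merge to one case), protein-altering gene recurrence with
optional UV-case exclusion, multi-hit counts, oncoprint matrices,
cross-species overlap, and the germline screen over the nine
angiosarcoma risk genes (*ERCC2, IDH1, IDH2, PIK3CA, POT1, PTEN, RB1,
TP53, XPC*).

**Synthetic cohorts** (`ffpesoma.synthetic`) — a first-class generator
that emulates the study design (duplicate FFPE cores, three caller
roles, concurrent tumor pairs, planted artifact classes, a population
panel, UV-profile skin samples, aligned reads with planted mismatches)
with a complete truth table, so every stage is testable offline.

## Worked example

`examples/02_paired_tumor_clonality.py` generates a visceral cohort of
14 concurrent cardiac/splenic pairs, filters it, and asks whether the
paired lesions are clonally related:

```
patient   heart-only  spleen-only  shared  permutation p
DV001              7            9      26  0.0010
DV002              9            7      26  0.0010
DV003              8            8      26  0.0010

cross-patient control (DV001 vs DV002): shared=0, p=1.000
```

Each pair shares ~26 of its ~33 somatic mutations (the generator plants
80% sharing), and re-pairing a lesion with other patients' tumors never
reaches that overlap (p = 1/(1+999)); tumors from different patients
share nothing. The concurrent lesions are one clone — a metastasis —
not independent primaries. The other examples cover the filter cascade,
UV-signature flagging, mismatch-rate QC, copy-number penetrance and the
cohort summary tables; each prints its results with a line of
interpretation.

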