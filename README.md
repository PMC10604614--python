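# ddcfdna

Genotype-free donor-derived cell-free DNA (dd-cfDNA) quantification and
transplant-cohort analysis, with a synthetic cohort generator that ties the
pieces together into a reproducible end-to-end study.

## The problem

After a kidney transplant, a fraction of the circulating cell-free DNA in
the recipient's plasma comes from the graft. That fraction — dd-cfDNA%,
typically well below 1% in a quiet graft — rises with graft injury and has
become a non-invasive marker of rejection, particularly antibody-mediated
rejection (AbMR). Commercial assays estimate it from a targeted panel of
~200 autosomal biallelic SNPs sequenced deeply from a *single*
post-transplant plasma sample, with **no donor or recipient genotyping**.
This package implements that estimator, the HLA eplet mismatch-load
computation used to characterise donor/recipient immunological disparity,
the tacrolimus-exposure metrics used as clinical covariates, and the
statistics of a cohort dichotomised at the 1.0% cutoff.

It is written for transplant immunologists and biostatisticians who want a
tested, open reimplementation of this analysis stack — and a simulator to
study its behaviour under known ground truth.

## The estimator

At each panel SNP the two most-read bases define a major (recipient) and a
minor (donor) base with minor share
`x = n_minor / (n_major + n_minor)`. Loci whose two-base shares fall inside
the 30–70% band are heterozygous in the recipient and discarded. The
remaining homozygous loci split into **background** (donor carries the same
allele; minor reads are sequencing error) and **informative signal**:
`x > ê + k·SE(ê)`, where `ê` is the sample's own background-error estimate
and SE its binomial standard error at the locus depth (k = 3).

Two averaging modes are exposed:

- `paper_faithful` — dd-cfDNA% = 100 · mean(x) over signal loci, the plain
  informative-SNP average. On outbred pairs roughly ⅔ of informative loci
  have a *heterozygous* donor contributing only f/2, so this mode
  underestimates by a predictable factor
  `Σ w_het/2 + w_hom / Σ (w_het + w_hom)` ≈ 0.66 under Hardy–Weinberg.
- `bias_corrected` (default) — subtracts the per-base error floor, assigns
  each signal locus to the donor-homozygous (≈ f) or donor-heterozygous
  (≈ f/2) cluster, doubles the heterozygous cluster, averages, and then
  inverts the analytically computed truncation/misassignment bias curve of
  that procedure. Recovers true fractions of 0.5–5% with |bias| < 2% of
  truth at depth 5000.

QC covers total reads, depth uniformity (CV across loci), and contamination:
a third genome scatters signal loci over a lattice of fractions that no
two-cluster fit can absorb, so loci inconsistent with the best two-cluster
partition at binomial noise scale are counted as outliers.

Downstream, the cohort module provides the Mann–Whitney U and uncorrected
Pearson chi-square group comparisons, ROC curves with DeLong confidence
intervals (AUC via the rank identity `AUC = U / (n⁺·n⁻)`), Rosendaal
time-in-therapeutic-range with exact segment crossing times,
CV% = (σ/μ)·100 with the sample (n−1) standard deviation, and a
Firth-penalised logistic regression as the covariate-adjusted association
analogue. HLA eplet mismatch loads are set differences
`|E_donor \ E_recipient|` over allele→eplet repertoires, per locus, per
class, or pooled.

## Worked example

Simulate a 42-patient cohort and quantify one sample:

```bash
$ ddcfdna simulate --n 42 --seed 7 --out demo
wrote cohort of 42 patients to demo

$ ddcfdna quantify --pileup demo/pileups/P0001.tsv
{
  "sample_id": "P0001",
  "dd_fraction_percent": 4.29,
  "classification": "elevated",
  "n_informative": 79,
  "background_error": 0.0007780186117878098,
  "mode": "bias_corrected",
  "qc": {
    "total_reads": 996976,
    "depth_uniformity": 0.5220093730411663,
    "n_outlier_loci": 0,
    "contamination_flag": false,
    "pass": true
  },
  "flags": []
}
```

This patient's simulated true donor fraction was 4.25%: 79 of the 202 SNPs
were informative (recipient homozygous, donor carrying the other allele),
the background error landed at 0.08% per locus, all QC checks passed, and
the estimate of 4.29% is classified *elevated* against the ≥ 1.0% cutoff.

Running the whole pipeline (`ddcfdna run-all --n 42 --seed 7 --out full`)
adds eplet loads, exposure metrics, the two group-comparison tables and
three ROC analyses; with this seed the cohort reports a median dd-cfDNA of
0.63%, AbMR discrimination AUC 0.90 (95% CI 0.80–1.00), and a class II
eplet mismatch load of 48 in the elevated group versus 19 below the cutoff
(p < 0.001) — the association the analysis is designed to expose.

Every stage is also importable directly:

```python
from ddcfdna import simulate_cohort, SimulationConfig, estimate_dd_fraction

cohort = simulate_cohort(SimulationConfig(n_patients=42, seed=7))
result = estimate_dd_fraction(cohort.patients[0].sample)
print(result.dd_fraction_percent_rounded, result.qc.passed)
```

## Layout

- `src/ddcfdna/panel.py`, `simulate.py` — SNP panel and synthetic cohort
  generator (genotypes, pileups, typings, trough series, outcome labels)
- `src/ddcfdna/quant.py` — the dd-cfDNA% estimator and QC
- `src/ddcfdna/eplets.py` — antigen mismatches and eplet mismatch loads
- `src/ddcfdna/exposure.py` — Rosendaal TTR, CV%, C/D ratio, threshold flags
- `src/ddcfdna/stats.py` — group tests, ROC/DeLong, Firth logistic, tables
- `src/ddcfdna/pipeline.py`, `cli.py`, `io.py` — end-to-end runs, CLI,
  plain-text formats
- `docs/methods.md` — models, assumptions, calibrations and limitations
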