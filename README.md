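# editome

A-to-I RNA editome analysis from RNA-seq variant calls: site discovery,
editing-level quantification, differential-editing statistics, and
cross-cohort integration — with a synthetic-cohort generator so the entire
pipeline is testable without any data download.

## The problem

Adenosine-to-inosine (A-to-I) RNA editing, catalyzed by ADAR enzymes, is the
most common RNA modification in the human brain. Inosine is read as
guanosine, so editing appears in RNA-seq as A>G variants on the coding
strand (T>C on the reverse strand of the reference). Profiling how editing
changes between disease and control groups across brain regions — for
example in sepsis-associated encephalopathy, where the hippocampus and
prefrontal cortex respond differently — requires a chain of careful steps:
separating true editing sites from germline SNPs and sequencing errors,
quantifying per-site editing levels from allele counts, testing for group
differences with models that respect read depth, and intersecting
differential gene lists across regions and cohorts.

This package implements that chain for anyone analyzing VarScan-style
per-sample VCFs from bulk RNA-seq: computational biologists profiling
editomes, and methodologists who need a fully simulated test bed.

## The model

**Site discovery.** A call is retained when mean base quality ≥ 25,
alternative-allele depth ≥ 2, total depth ≥ 10 and alternative allele
frequency (AAF) ≥ 1% (all inclusive). A retained call is an A-to-I
candidate when it is A>G inside a `+`-strand gene or T>C inside a
`-`-strand gene. High confidence is disjunctive: the site is kept if it is
**known** (exact coordinate in a REDIportal-style catalog) *or* it is a
novel coding-strand A-to-G call passing a QC cascade — SNP-interval
overlap, homopolymer run ≥ 5 nt, splice-junction proximity (± 4 nt), and
multi-allelic positions — with a per-filter audit table.

**Quantification.** The editing level at a site is the AAF of the A-to-G
call in coding-strand orientation,

$$\hat\theta = \frac{G}{A + G},$$

assembled into a sites × samples matrix; a cell with no passing call is 0
when a coverage table shows depth ≥ 10 (covered, unedited) and missing
otherwise. Per-sample transcriptome-wide averages are unweighted site means.

**Differential editing.** Per site, alternative counts $y_j \sim
\mathrm{Bin}(n_j, \pi_{g(j)})$ with $\mathrm{logit}(\pi) = \beta_0 +
\beta_1\,\mathbb{1}[\text{sepsis}]$; the likelihood-ratio test compares the
group model to the intercept-only null, $\Lambda = 2(\ell_1 - \ell_0) \sim
\chi^2_1$. For a single two-level factor the MLEs are the group-pooled
proportions, so the fit is closed form (a quasi-binomial option rescales
the statistic by the Pearson dispersion). Group comparisons of per-sample
averages use a Gaussian GLM with the same nested-model LRT. BH q-values
are always reported; default selection mirrors raw p < 0.05.

**Integration.** *Key genes* are genes differential in ≥ 2 named
comparisons (regions × cohorts), from exact set algebra with a full Venn
decomposition. Editing–expression association uses Spearman's ρ with an
**exact permutation p-value for n ≤ 8** (cohort arms of 7 are too small for
the t-approximation). The validation arm is quantified with the
$2^{-\Delta\Delta C_t}$ method (normalized to a housekeeping gene and a
calibrator condition) and the Sanger chromatogram peak ratio $G/(A+G)$.

**Synthetic cohorts.** `editome.synthdata` generates a toy annotated genome
(GFF3/BED/FASTA), planted edit/SNP/error sites, and per-sample VCFs with
negative-binomial coverage and binomial counts over logit-normal editing
probabilities — including per-site disease effects, a region-level shift,
and optional editing–expression coupling — plus a ground-truth table for
recovery tests. Identical seed + config reproduces fixtures byte for byte.

## Worked example

```bash
python examples/01_simulate_cohort.py
python examples/03_differential_editing.py
```

prints (seed 1, 200 planted edit sites, 7 vs 7 per region):

```
hippocampus: mean editing sepsis-control difference -0.0076  (GLM LRT p=0.0239)
prefrontal_cortex: mean editing sepsis-control difference +0.0098  (GLM LRT p=0.00485)
differential sites at raw p<0.05: 28 in 22 genes
PC1 of the differential sites explains 47.1% of the variance
```

The hippocampus average drops because the generator plants a region-level
loss of editing in that region's sepsis samples on top of per-site disease
effects shared by both regions; the prefrontal cortex only sees the
(positive) per-site effects. The PC1 fraction summarizes how much of the
variance among samples the differential sites capture. The other examples
cover site discovery with the QC audit (`02`), key-gene intersection,
exact-permutation Spearman, 2^-ddCt and Sanger ratios (`04`), and the full
pipeline with its deterministic JSON summary (`05`).

The same stages are scriptable from a shell:

```bash
editome simulate --seed 1 --out scratch/fix
editome run --config cfg.yaml      # discover -> quantify -> test -> intersect
```

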