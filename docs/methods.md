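# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical conventions, and the design decisions behind `editome`.

## Site discovery

A per-sample variant call is retained when **all** of: mean base quality ≥
25, alternative-allele depth ≥ 2, total depth ≥ 10, AAF ≥ 1% (boundaries
inclusive). Orientation is resolved catalog-first: if the coordinate is in
the known-site catalog and the change matches A>G on the catalog strand,
the site is *known* (this rescue also recovers known sites outside gene
bodies, where no coding strand can be inferred). Otherwise the strand comes
from the host gene: A>G in a `+` gene or T>C in a `-` gene is an A-to-I
candidate; positions covered by genes on both strands are undecidable
without read-strand information (which VCF lacks) and are dropped and
counted. Multi-allelic VCF records are dropped by default (the editing
model is biallelic A/G); a split policy exists.

High confidence is disjunctive — known sites bypass the QC cascade but must
still pass call-level thresholds (thresholds define callability; the QC
cascade defines novelty screening). The cascade applies, in order, to novel
sites only:

1. **SNP overlap** — exclusion intervals (BED), e.g. a dbSNP track;
2. **homopolymer** — reference run of ≥ 5 identical bases containing the
   site (alignment slippage artifacts);
3. **splice junction** — within 4 nt of an internal exon boundary
   (spliced-alignment artifacts);
4. **multi-allelic** — more than one alternative allele observed at the
   position across samples.

Each filter is individually toggleable, and the audit table satisfies
`input = retained + Σ removed` by construction. The exact composition of a
QC cascade varies between published editome pipelines; this set is the
common denominator and the audit table makes the effect of each rule
transparent. Whether a site must pass thresholds in a minimum number of
samples before entering the union is exposed as `min_samples_called`
(default 1).

Functional annotation uses the fixed precedence CDS > 3'UTR > 5'UTR >
noncoding exon > intron > intergenic; repeat class is Alu if any covering
repeat interval is an Alu, else other_repeat, else none.

## Editing levels

Level = alt/(ref+alt) = G/(A+G) in coding-strand orientation. Cells
without a passing call are **0** when an external coverage table shows
depth ≥ `min_depth` (covered but unedited) and **missing** otherwise —
VCFs report only variant positions, and conflating "unedited" with
"unsequenced" would bias averages downward. `min_depth` defaults to the
threshold set's total-depth cutoff (10) so "covered" coincides with
callability. Per-sample averages are unweighted means over non-missing
sites (a read-weighted or complete-sites-only variant is a flag, not the
default, since site coverage is heteroscedastic and the choice is not
forced by anything in the data).

## Differential editing

Counts: `alt_j ~ Binomial(depth_j, pi_g(j))` with a logit link and disease
status as the only covariate. With one two-level factor the MLE of each
group's probability is its pooled proportion, so the deviance difference

`LRT = 2 * [ ll(p_case, p_control) - ll(p_pooled) ]  ~  chi^2(df=1)`

is closed form; the implementation is vectorized across sites and verified
in the tests against an iteratively fitted GLM (statsmodels) and a
brute-force likelihood grid. Conventions for degenerate sites: zero (or
saturated) alternative counts overall give p = 1 and LRT = 0 (no
information); a group proportion at 0 or 1 caps |beta| at 15 logits and
flags the row instead of reporting infinities; fewer than 2 samples with
data in either group marks the site untestable (p missing). A
quasi-binomial option divides the statistic by the Pearson dispersion
(floored at 1) with an F(1, n−2) reference for overdispersed cohorts.

Binomial-on-counts was chosen over Gaussian-on-levels for the per-site test
because it weights samples by read depth; the Gaussian GLM is used where
the response is genuinely continuous (per-sample average editing,
expression), fitted by the same nested-model LRT (`n·log(RSS0/RSS1)` ~
chi² df 1). Both families are available per site via `family=`.

Multiple testing: BH q-values are always computed and reported, but default
*selection* is raw p < 0.05, matching the significance annotations common
in editome studies; selecting on q is one flag away.

PCA of differential sites: site-mean imputation of missing cells, site
(column) centering, SVD; variance fractions are normalized squared singular
values, so they sum to one and are invariant to duplicating samples.

## Integration

Key genes are genes appearing in ≥ k (default 2) of the named
differential-gene sets; the report keeps the full Venn decomposition so
inclusion–exclusion identities hold exactly. Spearman's rho uses average
ranks; for n ≤ 8 the two-sided p-value enumerates all n! orderings exactly
(at n = 7, the cohort arm size, the t-approximation is unreliable), with a
1e-12 tolerance when comparing |rho| values so ties in the discrete null
distribution are counted correctly. 2^-ddCt normalizes the target Ct to the
housekeeping reference per sample and to the calibrator condition's mean
dCt, which forces the calibrator group's geometric-mean fold change to 1.
Sanger editing levels use the standard peak-height ratio G/(A+G); the
chromatogram peaks enter as numbers (file parsing is out of scope). A
replication cohort is just another cohort label in the sample sheet — no
cohort-specific logic anywhere.

## Synthetic cohorts

The generator emulates a two-region case/control brain cohort:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 7 | samples per group per region (7 sepsis vs 7 controls) |
| `regions` | hippocampus, prefrontal_cortex | region labels; the shift applies to the first |
| `n_edit_sites` | 500 | planted true editing sites (a desk-scale editome) |
| `n_snp_sites` / `n_error_sites` | 50 / 50 | SNP contaminants / error sites |
| `coverage_mean`, `coverage_dispersion` | 50, 8 | negative-binomial read depth |
| `baseline_beta_a/b` | 2, 6 | Beta baseline editing level, truncated to [0.05, 0.95] |
| `site_sd_logit` | 0.15 | between-sample biological noise (logit SD) |
| `frac_differential`, `disease_effect_logit` | 0.05, 1.0 | planted per-site disease effects |
| `region_shift_logit` | −0.12 | region-wide editing loss in sepsis samples of region 1 |
| `frac_known`, `frac_alu` | 0.85, 0.80 | catalog membership / Alu coverage of edit sites |
| category weights | 0.80 intron, 0.12 3'UTR, 0.03 CDS, 0.02 5'UTR, 0.01 noncoding exon, 0.02 intergenic | placement of edit sites |

These defaults follow the structure brain editomes show — editing
concentrated in introns and 3'-UTRs of protein-coding genes, mostly inside
Alu elements, >80% cataloged — at a problem size (hundreds of sites, 28
samples) chosen so every simulation-based test re-derives its expectations
in seconds. The −0.12 logit region shift is the value whose expected
absolute editing-level change under the baseline distribution is −0.02
(`logit_shift_for_level_shift` computes this mapping by quadrature +
root-finding), i.e. a small but region-wide loss of editing activity.
SNP contaminants are germline-like (allele fraction ≈ 0.5 in every sample,
so the SNP-exclusion rule is what removes them, not the statistics); error
sites emit alternative reads at rate 0.002, below the 1% AAF threshold in
expectation. A fixed 8% of non-Alu edit sites receive a non-Alu repeat
interval so the other_repeat class is populated.

Counts are binomial given a logit-normal per-sample editing probability —
effectively beta-binomial-like overdispersion — so the AAF-based
quantification faces realistic dispersion. Coordinates: VCF/catalog/GFF3
are 1-based (GFF3 inclusive), BED is 0-based half-open; round-trip tests
enforce both.

Deliberate simplifications (what passing tests do **not** show about real
data): no read-level artifacts (the out-of-scope upstream of alignment,
duplicate marking and recalibration is assumed done), uniform two-exon gene
structure, no hyper-editing clusters, no strand-ambiguous antisense
transcription beyond deliberately overlapping test genes, sites placed away
from splice junctions and homopolymers (QC-filter behavior is tested on
purpose-built cases instead), no covariates beyond disease status (the
model uses disease status as the only independent variable, so the
simulator plants none), and independence between sites (no co-editing
correlation). Repeat intervals are truncated so they never cover a
neighboring simulated site, keeping the truth's repeat class exact.

## Calibration conditions

The null-calibration checks (type-I error in [0.03, 0.08] at alpha 0.05; KS
uniformity) define the null as *all* planted effects zero, including the
between-sample logit noise: the plain binomial LRT is calibrated under the
binomial model, and non-zero `site_sd_logit` is itself a planted random
effect that inflates the statistic (that regime is what the quasi-binomial
option is for, and a dedicated test verifies it is the more conservative of
the two there). Power and recovery checks keep the default noise.

## Determinism

All randomness flows from one `numpy.random.Generator`; fixtures are byte-
identical for identical (config, seed), file writers iterate in sorted
order, and the pipeline's summary JSON rounds floats to 6 digits and sorts
keys, so `editome run` is byte-deterministic given its inputs. The
acceptance script derives all sub-seeds from `--seed` via
`numpy.random.SeedSequence`.
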