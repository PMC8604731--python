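# Methods

`mesomics` implements the genomic and immunologic correlates-of-response
analytics used in chemo-immunotherapy studies of malignant pleural
mesothelioma (MPM): per-tumor mutation and clonality metrics,
allele-specific copy-number landscape scores, neoantigen and HLA-divergence
immunogenomics, T cell receptor (TCR) repertoire statistics with
antigen-specific clonotype calling, and an outcome-association layer. A
seeded synthetic-cohort generator supplies complete per-patient inputs with
planted, recoverable effects so every stage is testable without
controlled-access sequencing data.

## Mutation clonality (CCF)

The cancer cell fraction model assumes a tumor cell population of purity
`α` in a diploid normal background. For a mutation with variant allele
fraction `v` at a locus of tumor total copy number `C`, present at
multiplicity `m` in a fraction `ccf` of tumor cells:

    v = α · m · ccf / (α·C + 2(1−α))

Multiplicity is estimated as `round(v/α · (αC + 2(1−α)))` clamped to
`[1, C]`; the CCF point estimate is capped at 1.5 so read-sampling noise
above 1 is absorbed rather than raised as an error. The confidence interval
propagates the exact (Clopper–Pearson) binomial interval of `v` through the
same formula at the fitted multiplicity. A mutation is called clonal when
`ccf ≥ 0.9` or the interval's upper bound reaches 1; both the cutoff and
the CI level are configurable. The cutoff is a design choice — common
practice for dichotomizing clonal versus subclonal mutations — since no
single canonical value exists.

Mutations falling in segments of total copy number exactly 1 are counted as
"single-copy-region" mutations; loci without segment coverage cannot be
assigned a copy state and are reported separately rather than counted.

## Copy-number landscape

All segment arithmetic uses 1-based inclusive coordinates (SEG convention;
length = end − start + 1), and adjacent segments with identical
(total, minor) copy state are merged before every metric so that
segmentation granularity cannot change biology-level results (a tested
invariant). Sex chromosomes are excluded; the assembly covers autosomes
only, with minor-allele semantics uniform across samples.

* **Aneuploidy.** LOH fraction: length-weighted fraction of the covered
  genome with minor copy 0 and at least one copy retained. Allelic
  imbalance: major ≠ minor. Breakpoints: junctions between consecutive
  same-chromosome segments where the joint (total, minor) state changes;
  chromosome ends are not breakpoints. Copy-state entropy: Shannon entropy
  (nats) of the length-weighted total-copy-number distribution. Breakpoints
  are counted on the allele-specific state because it is the finer, stated
  data model.
* **HRD scores.** Telomeric allelic imbalance (TAI): allelic-imbalance
  segments touching a chromosome end without crossing the centromere, no
  minimum size. LOH score: LOH segments ≥ 15 Mb not spanning their whole
  chromosome. Large-scale state transitions (LST): junctions between
  segments each ≥ 10 Mb, gap ≤ 3 Mb, different copy state. HRD-sum is their
  total (asserted additively). Thresholds are in bases of the active
  assembly and scale with it.
* **Arm events.** The copy-neutral reference is the sample ploidy rounded
  to the nearest integer. A segment is a gain above it, a loss below it,
  and LOH where the minor allele is absent; LOH is independent of
  gain/loss, so an arm can carry both a loss and an loh label. An arm is
  called only when ≥ 90% of its length carries the status.
* **Arm-recurrence permutation test.** For each event type, every
  permutation replicate redraws each sample's observed event-arm count
  uniformly without replacement over the 39 evaluable arms (acrocentric p
  arms excluded), preserving per-sample aneuploidy levels. Preserving
  counts per event type (rather than pooled) retains more structure;
  pooled-mode testing is available by passing an OR-ed event matrix.
  Per-arm p = (1 + #{replicates ≥ observed}) / (1 + B), BH-adjusted across
  arms. This estimator is valid but discrete and slightly conservative;
  `randomized=True` returns exact randomized ("fuzzy") p-values — uniform
  under the null by exchangeability of the observed statistic with the
  replicates — used for calibration studies, while the conservative
  estimator remains the default output.
* **Near-haploidization (GNH).** Flagged when the LOH fraction reaches 0.80
  (configurable; no canonical threshold exists, so the default is a design
  choice).
* **Background loss rates.** An arm is haploid (euploid) when ≥ 75% of its
  length has total copy 1 (total 2, minor 1). Haploid loss rate: bases at
  copy 0 within haploid arms over total haploid arm length. Euploid loss
  rate: (2 × bases at copy 0 + bases at copy 1) over total euploid arm
  length. The euploid formula counts lost allele-copies, so its natural
  maximum is 2 rather than 1; it is implemented verbatim, and a
  length-normalized variant can be derived by halving.
* **Focal events.** Total copy 0 (homozygous deletion) or > 3 × ploidy
  (amplification, strict); abutting qualifying segments of the same kind
  are merged before the strict < 30 Mb size test.

## Immunogenomics

For each missense mutation, all 8–11-mer (MHC class I) and 15-mer
(class II) mutant peptides containing the altered residue are enumerated
from a ≥ 29-residue protein context window (truncated at protein ends) and
paired with each unique patient allele of the matching class. A pluggable
`AffinityScorer` assigns each peptide a deterministic score (lower =
stronger binding); peptides are ranked against a reference panel of 10,000
peptides per length per allele. The percentile is mid-rank with the query
included — `100·(#better + 0.5·#ties + 0.5)/(N+1)` — which is strictly
positive, at most 100, and unbiased under ties. A mutation is an
immunogenic mutation (IMM) for a class when any of its neopeptides for any
allele of that class ranks at or under the 1st percentile (configurable).
IMM counts are monotone non-increasing as the threshold tightens (tested).

The bundled `HashAffinityScorer` is a synthetic, deterministic
pseudo-affinity (vectorized FNV-1a hash mapped to [0, 1)), and the bundled
reference panel draws peptides uniformly over the 20 residues from a fixed
seed. Together they exercise the full ranking/calling machinery offline and
reproducibly; they are *not* binding predictors, and with uniform random
scores the synthetic IMM burden is strongly correlated with missense burden
by construction. Production use plugs a real predictor behind the same
contract.

HLA evolutionary divergence (HED) is the mean Grantham distance across
aligned positions of the two allele protein sequences at each class I locus
(A, B, C), zero for homozygotes, with the cumulative score the arithmetic
mean of the three loci. Distances are computed from the Grantham (1974)
formula constants and rounded to the published integer scale; a few entries
of the historically distributed table differ by a unit or two from exact
recomputation, and the formula is treated as authoritative. HED is computed
over the full provided allele sequence by default, with an optional residue
interval restriction (e.g. the peptide-binding domain). Class II HED is not
computed. Tumor unique-allele counts subtract heterozygous alleles flagged
with somatic LOH from the unique germline allele count; losing one copy at
a homozygous locus leaves the allele present and does not reduce the count.

## TCR repertoire

CDR3 amino-acid sequences must begin with C, end with F or W, and have at
least seven residues; failing clones are removed and frequencies
renormalized. Clonality is `1 − H/ln(richness)` with `H` the Shannon
entropy of productive frequencies (1 for a single clone); the ratio is
log-base invariant. The dominant-clone fraction sums the top
`ceil(0.05 · richness)` clones (minimum 1) after dropping clones under
0.01% abundance, with read-count ties broken lexicographically for
reproducibility.

Differential clonotype abundance between two samples tests every clone at
≥ 0.01% abundance in either sample with a two-sided Fisher exact test on
raw read counts, BH-adjusts across tested clones, and calls
expansion/regression at FDR < 0.01. Fold changes use a 0.5-read pseudo-count
on zero counts for direction and magnitude only — the test always uses raw
counts.

Antigen-specific clonotype calling over peptide-stimulation cultures
requires all five criteria: (1) significant expansion versus the no-peptide
control (Fisher/BH, FDR < 0.05, BH across the clonotypes of each
comparison); (2) significant expansion versus every other
peptide-stimulated culture; (3) odds ratio strictly greater than 5 versus
every other condition, with Haldane–Anscombe correction (+0.5 per cell)
only when a cell is zero; (4) at least 30 reads in the positive well;
(5) frequency at least twice the same clonotype's frequency in the
HIV-negative control. Conditions named in `exclude_from_pairwise` (e.g. a
viral-epitope positive-control pool) are omitted from the criterion-2/3
comparison set; by default all non-reference peptide conditions are
compared.

## Outcome statistics

Fisher's exact test is two-sided by the probability-mass rule, matching
standard statistical software. Binomial CIs are Clopper–Pearson; the
objective response rate counts CR+PR over all enrolled (non-evaluable
patients stay in the denominator). The Mann–Whitney test is exact for
combined n ≤ 20 (full-permutation when ties are present) and
normal-approximate with tie correction otherwise. Survival uses
Kaplan–Meier estimates, the log-rank test, and a Cox proportional-hazards
fit with Efron tie handling (via lifelines); the KM median is undefined
(NaN) when the curve never crosses 0.5. Tertile binarization uses the
empirical 2/3 quantile with linear interpolation, ties going to "low". The
trial-design helper returns the exponential hazard `ln 2 / median`; a
one-sided Wald test on the log failure rate is available behind an explicit
function since the original software's variance convention is not
published. BH adjustment is applied wherever an FDR is reported; raw
two-sided p-values are used elsewhere.

## Synthetic cohort generator

The generator defines the study conditions for every recovery experiment.
Defaults mirror the trial's printed cohort structure: 55 patients,
histology mix 41/7/6/1 (epithelioid/sarcomatoid/biphasic/desmoplastic),
response rates 65.9% / 28.6% (epithelioid / non-epithelioid), non-responder
missense mean 18 with a responder multiplicative shift of 23/18, and a
near-haploidization probability of 3/40.

* **Burdens** are negative binomial (dispersion 10) with the responder
  shift applied to the mean; consequence classes beyond missense are
  Poisson at fixed rates.
* **Segments** tile a 1/20-scale 22-autosome assembly (arm/centromere
  geometry preserved; ~154 Mb genome chosen for desk-scale per-base oracle
  tests) gap-free per chromosome, with per-segment LOH probability set by a
  per-patient target; GNH tumors are guaranteed at least the configured
  minor-copy-0 fraction (0.88) by flipping the largest non-LOH segments if
  the random draw falls short. Read counts for mutations follow the CCF
  model at the planted purity and local copy number.
* **Repertoires** draw clone frequencies from a symmetric Dirichlet
  (optionally a power-law tail) and sample reads multinomially (depth
  10^5); the concentration parameter is the single clonality knob, shifted
  by a factor 0.25 in the short-OS (< 12 months) stratum so shorter
  survival pairs with more clonal repertoires. All generated CDR3s pass QC
  by construction ('C' + 5–18 random residues + 'F'/'W').
* **Survival** is exponential (baseline median 16 months) with
  administrative censoring at 36 months and a planted hazard ratio of 0.5
  on the germline-carrier flag. The carrier flag is a *balanced* planted
  covariate (prevalence 0.5): it exists to validate hazard-ratio recovery
  at the precision the validation experiments demand, and is not an
  estimate of germline-mutation prevalence.
* **Culture fixtures** plant antigen-specific clonotypes that satisfy all
  five specificity criteria by construction, and negatives that each
  violate exactly one named criterion (too few reads, insufficient odds
  ratio, matched background expansion, no significant expansion), recorded
  in the truth record. A single shared filler clone pads every well to
  comparable depth so padding can never look condition-specific.

Identical config and seed reproduce byte-identical tables (fixed-precision
writers). The truth record carries every planted effect and states
explicitly that the distributional forms are stand-ins: real cohorts carry
mutation-signature structure, segment-size distributions, V/J usage,
covariate correlations and measurement artifacts that the generator does
not emulate. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated models, not performance on real data.

## Problem sizes and numerical choices

Recovery experiments run 50 seeds at n = 200 (burden ratio within
[1.3, 1.7]; Cox HR in [0.35, 0.7] and 95% CI covering 0.5, each in ≥ 90% of
seeds; clonality-shift direction in ≥ 90%). Oracle agreement uses 100
random toy-genome profiles against per-base scans, permutation calibration
uses 200 replicates of 8-sample null cohorts with 199 permutations each,
and the end-to-end reproducibility check runs 100 patients twice with 1,000
permutations and the full 10,000-peptide panel. Exact-test oracles
enumerate all 2×2 tables up to n = 40 and Mann–Whitney assignments up to
n = 18. Cox convergence and tie handling follow lifelines defaults;
degenerate fits (e.g. no events in a group) return NaN hazard ratios rather
than raising.

## Known limitations

* The affinity scorer and reference panel are synthetic; IMM burdens on
  synthetic cohorts have no biological calibration.
* HLA allele "alignment" is by equal-length sequences; no multiple
  sequence alignment is performed, matching the input contract that
  sequences arrive pre-aligned.
* The euploid background loss rate is reported on its verbatim 0–2 scale.
* Whole-exome realism (trinucleotide contexts, signature structure, indel
  spectra) is out of scope for the generator, as are read-level data.
* The arm permutation null treats arms as exchangeable units and ignores
  arm length differences, matching the stated 39-slot redistribution
  scheme.
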