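# Methods

`caprapop` implements a complete population-genomic workflow for diploid
SNP-array genotypes of two (or more) labeled populations — the setting of a
small-ruminant breed survey: quality control, diversity and inbreeding
statistics, structure inference, runs of homozygosity, linkage-disequilibrium
decay and effective population size, and construction and evaluation of a
breed-discriminatory marker panel. This note records the models, the
parameter conventions, the synthetic-data design and the numerical choices.

## Genotype model and I/O conventions

Genotypes live in a samples × markers dosage matrix counting copies of
`allele_b`, defined as the **second allele observed in file order** when
reading PLINK text. The counted allele is stored explicitly in the marker
record, so all statistics are invariant to allele labeling and a
read → write → read cycle is the identity. Missingness is the sentinel −1.
PLINK binary files are read and written in SNP-major mode (magic bytes
`6C 1B`, mode `01`, four 2-bit genotypes per byte, zero-padded); sample-major
mode is rejected explicitly. Base-pair positions are 1-based as in .map/.bim,
and all segment lengths are computed as `end_bp − start_bp`, matching PLINK's
kb reports. Chromosome labels are strings; nothing is hard-coded to the goat
autosome count, though defaults (29 autosomes) reflect it.

## Quality control

Samples are filtered first (call rate > 0.9, strict), then SNPs in a fixed
order — unmapped, sex-linked, call rate < 0.98, MAF < 0.01, HWE p ≤ 1e−6 —
with each excluded SNP attributed to the *first* filter it fails. The net
exclusion count is order-insensitive; the per-filter breakdown is not, which
is why the attribution order is fixed and reported. The Hardy–Weinberg test
is the standard exact test: conditional on allele counts, the heterozygote
count follows a hypergeometric-type distribution evaluated by a downward
recurrence over admissible het counts (rescaled when terms grow large); the
two-sided p-value sums all outcomes no more probable than the observed one.
HWE is computed on the pooled cohort by default (QC precedes any breed-wise
analysis), with a per-breed switch available.

## Diversity and inbreeding

* **Ho/He**: per-SNP observed heterozygote fraction and Nei's unbiased
  expected heterozygosity `(2n/(2n−1))(1 − p² − q²)` over called genotypes.
  SNPs with fewer than two called genotypes in a breed are skipped and
  counted. **π** is reported as the mean unbiased per-site heterozygosity
  over the usable SNPs (the mean pairwise difference per SNP site); the
  skip-and-count rule is this package's declared handling of partially
  genotyped loci.
* **F_IS**: per-individual method of moments,
  `F = (O_hom − E_hom)/(L − E_hom)` over the individual's called SNPs, with
  `E_hom = Σ_j [1 − 2p_j q_j (2n_j/(2n_j−1))]`. Allele frequencies default to
  the individual's own breed cohort ("individual within subpopulation"); a
  pooled mode is one flag away, since reasonable tools differ here.
* **F_GRM**: VanRaden method-1 GRM, `G = ZZ'/(2Σ p_j(1−p_j))` with
  `Z = dosage − 2p` and missing imputed to the mean (Z = 0); inbreeding is
  `diag(G) − 1`, computed within breed by default.
* **FST**: the Weir–Cockerham (1984) variance-components estimator with
  components a (among populations), b (among individuals within), c (within
  individuals), computed per SNP from sample sizes, allele frequencies and
  observed heterozygosities. Per-SNP θ = a/(a+b+c) may be negative and is
  *not* clamped (the count of negative loci is itself informative); the
  global value is the ratio of sums. SNPs monomorphic across all populations
  or with fewer than two called genotypes per population are excluded from
  both the per-SNP list and the sums.

## Structure

PCA operates on the variance-standardized matrix (per-SNP scaling
`1/√(2p(1−p))`, missing → 0); eigenvector signs follow the
largest-magnitude-entry-positive convention, and variance percentages are
reported under both normalizations (all components, and the computed top-k)
because published percentages rarely state which was used.

Admixture uses the standard binomial mixture likelihood for unlinked
genotypes, maximized by plain EM (frappe-style). EM has the same stationary
points as quasi-Newton accelerations; at desk scale the simpler update is
preferred, with multi-start by seed list and a per-iteration non-decreasing
log-likelihood guarantee that is asserted in tests. K is chosen by
masked-entry cross-validation: a fraction (default 10%) of called entries is
hidden, the model refitted, and hidden dosages predicted as `2Σ_k q_ik p_kj`;
the CV error is the RMSE over hidden entries averaged over folds. This is an
*analogue* of deviance-fold CV, not a replica of any specific tool's
procedure. Label switching in truth comparisons is resolved by the best
column permutation (Hungarian assignment).

## Runs of homozygosity

Detection follows PLINK `--homozyg` scanning-window semantics with
parameters: window of 15 SNPs, at most 1 heterozygous and 1 missing call per
window, per-SNP hit-rate threshold 0.05, minimum 15 SNPs and 1 Mb per final
segment, maximum 1 Mb gap between consecutive SNPs, and a minimum density of
one SNP per 50 kb. The four named parameters are the study design; the
remaining knobs are PLINK defaults, except the minimum SNP count, which is
set equal to the window size because a 100-SNP minimum cannot yield 1-Mb
segments on a ~50K chip. All parameters are explicit in `ROHParams` and
echoed in outputs. F_ROH divides summed segment length by the SNP-covered
autosome length (sum over chromosomes of last − first SNP bp), with
<10 / 10–20 / >20 Mb bins that sum exactly to the total. The length-class
spectrum uses the six AdaptMap classes with left-closed boundaries,
normalized by total ROH length in Mbp. Per-chromosome coverage is
`(Σ ROH Mbp / N)/chromosome Mbp × 100` with N the number of animals carrying
a ROH there (0 is reported flagged).

## LD and effective population size

r² is the genotypic (composite) squared Pearson correlation of unphased
dosage vectors over jointly called samples — what PLINK computes without
phasing — for all intra-chromosomal pairs between 1 kb and 1 Mb apart; pairs
with under 3 complete observations or zero variance are skipped and counted.
The decay curve fits `E[r²](d) = 1/(1 + 4Nc(d)) + 1/(2n)` by nonlinear least
squares; the recombination map defaults to 1 Mb = 1 cM and is configurable.
The Ne trajectory inverts the same expectation per log-spaced distance bin:
`Ne = (1/4c)(1/r²_adj − α)` with `r²_adj = mean r² − 1/(2n)` and
`t = 1/(2c)` generations; α defaults to 1 (2 and 2.2 are accepted). Bins at
or below the α floor are flagged rather than extrapolated.

## Discriminatory panels and assignment

Three panel routes: (i) SNPs at or above the 0.995 linear-interpolation
quantile of defined per-SNP θ; (ii) the intersection of the top-200 SNP
lists under Δ = |p₁ − p₂|, θ, and Rosenberg's informativeness for assignment
`In = Σ_alleles [−p̄ log p̄ + (1/K) Σ_k p_k log p_k]` (ties broken by snp_id
for determinism); (iii) the same intersection built on a stratified 50/50
training split (seeded) and evaluated by assigning the held-out half. The
consensus panel is the three-way intersection; all pairwise overlap counts
are reported because the Venn denominators differ between conventions.

Assignment likelihoods follow GeneClass2 conventions: the frequency-based
criterion multiplies Hardy–Weinberg genotype probabilities from breed allele
frequencies with a 0.01 floor for unseen alleles; the Bayesian criterion is
the Rannala–Mountain posterior-predictive genotype probability under a
per-allele Dirichlet(1/k) prior (closed form for biallelic loci, verified
against quadrature). Self-assignment uses leave-one-out frequencies for the
individual's own breed to avoid optimistic bias. Exclusion tests simulate
1,000 multilocus genotypes from the candidate breed's frequencies (Paetkau
resampling) and report the smoothed rank p-value `(count+1)/(n_sim+1)` with
α = 0.001; the first-generation-migrant statistic is
`log10 L_home − log10 L_max`.

## Synthetic data: what it emulates and what it does not

Population allele frequencies follow the Balding–Nichols model
(`p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`), giving closed-form control of the
expected FST without an external simulator; ancestral frequencies are
uniform on a configurable MAF range mirrored about 0.5. Genotypes are
binomial draws given each individual's ancestry-weighted frequency, so
**sites are independent given ancestry: there is no background LD**.
Consequently LD/Ne estimation is validated on identities and on pairs
generated exactly from the decay curve, not on recovering an Ne trajectory
from simulated genotypes, and the reported mean r² of simulated cohorts
reflects sample-size noise (≈ 1/(2n)), not chip-like LD. Admixed individuals
receive a fixed ancestry vector; missingness is i.i.d.

Autozygosity is injected as explicit segments (exponential lengths around a
configurable mean, minimum 1.5 Mb) in which one allele per SNP is drawn and
doubled. Each injected span is delimited by two heterozygous sites on either
side (one more than the detector's per-window het allowance): without an
informative flanking heterozygote the apparent tract extends into chance
homozygosity, which is a property of the data, not of the detector, and
would make the recorded truth unrecoverable in principle. Defaults emulate a
typical two-breed chip survey: 32 and 40 does, divergence FST ≈ 0.04, 29
autosomes, a designated admixed group, light missingness.
Test and acceptance runs scale the genome to fewer, densely genotyped
chromosomes (~25–40 kb marker spacing, matching a 50K chip's density) so
window-based ROH calling and 1-Mb LD windows are exercised realistically at
desk scale.

Passing tests on these cohorts demonstrates estimator correctness and
recovery under the stated generative model; they do not certify behavior
under real-chip artifacts (clustered missingness, genotyping batch effects,
background LD, ascertainment bias of array SNPs).

## Numerical choices and degenerate inputs

* HWE recurrence rescaled at 1e280 to avoid overflow; p capped at 1.
* Monomorphic markers get a placeholder counted allele and dosage 0.
* EM frequencies clipped to [1e−9, 1 − 1e−9]; CV masks are redrawn (up to
  20 times) if any SNP would lose all called entries.
* Per-SNP θ is NaN (excluded, counted) for SNPs undefined under the
  estimator's preconditions; the global ratio uses defined SNPs only.
* Quantile panels use linear interpolation; full-tie inputs return the whole
  set at the threshold.
* Assignment arg-max ties break by breed label order and are flagged.
* All randomness flows through explicit integer seeds; pipeline stages derive
  sub-seeds from one master seed, and reruns are byte-identical.

## Known limitations

* No background LD in simulated genotypes (see above).
* ROH boundary resolution is one inter-SNP gap at best; sparser maps widen
  it, and marker maps sparser than ~50 kb/SNP conflict with the default
  density filter by construction.
* The admixture EM can need many iterations near weak divergence
  (FST ≲ 0.01); multi-start is advised there.
* Sex chromosomes are dropped at QC; no X-specific statistics.
* Two-breed panels only; the informativeness statistic itself supports K > 2.
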