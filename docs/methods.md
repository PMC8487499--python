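# Methods

This note documents the models, estimators and numerical choices behind
`sexlink`, and what the simulator does and does not emulate.

## Genotype calling and marker QC

Diploid genotypes are called per cell from the two allele depths (r, a) by
maximising the binomial read likelihood with symmetric per-read miscall
rate e (default 0.01): per-read ALT probabilities e (hom ref), ½ (het) and
1−e (hom alt). The shared binomial coefficient cancels, so only the three
log-likelihoods are compared; exact ties go to het (between the two
homozygotes a tie implies r = a, where het already dominates for any
e < ½). Cells with total depth below `min_depth` (default 5 reads) are
missing. Calling is monotone: adding reads of one allele never moves the
call away from that allele's homozygote.

Two marker filters are used, both computing MAF from called genotypes only
(denominator 2 × called accessions): association scan — call rate ≥ 0.75
and MAF strictly > 0.05; kinship estimation — call rate ≥ 0.95 and
MAF ≥ 0.01. Multi-allelic VCF records are skipped by default
(`split_multiallelic` splits them instead); coordinates stay 1-based
end-to-end. No imputation is performed anywhere except where explicitly
noted below.

## Exact association test

Per marker, the 2×(2–3) table of sex × genotype class is tested for
independence with the Freeman–Halton exact test: the p-value is the sum of
hypergeometric point probabilities, over all tables with the observed
margins, that do not exceed the observed table's point probability. All
arithmetic is in log space with log-gamma factorials, so p-values far below
double underflow of the naive product form (10⁻⁷⁰ and smaller) are exact to
machine precision. The "as or more extreme" comparison uses a relative
tolerance of 10⁻¹² in log space so floating-point jitter cannot exclude
exactly tied tables. Degenerate tables (a zero margin after dropping empty
genotype columns) return p = 1 by convention. Significance uses the
Bonferroni bound α/m (α = 0.05) — deliberately conservative and the only
multiplicity control offered; there is no FDR option and no genomic-control
inflation factor.

The test suite verifies the implementation against exhaustive enumeration
with exact integer tie decisions for *every* 2×2 and 2×3 table with n ≤ 25,
and against scipy's (exact) 2×2 path.

## Mixed linear model

Sex is modelled as a 0/1 Gaussian response (F = 1): y = Qγ + xβ + u + e,
u ~ N(0, σ²g K), e ~ N(0, σ²e I). A Gaussian model for a binary trait is a
deliberate fidelity choice — it is what the standard GWAS MLM tools do —
not a claim of distributional correctness; the exact test remains the
primary scan. K is a VanRaden-style realised-relationship matrix from
mean-imputed, centered dosages, rescaled to mean diagonal 1 (positive
semidefinite by construction; a bending helper clips numerically negative
eigenvalues). Structure covariates Q are an intercept plus the top-q
principal components of the centered dosage matrix (default q = 2; the
study population's externally derived structure is not recoverable, so PCA
stands in).

After one spectral decomposition of K, the variance ratio δ = σ²e/σ²g is
re-estimated by REML for every marker — no P3D/EMMAX shortcut — via a
61-point log₁₀ grid on [−5, 5] followed by golden-section refinement of the
bracketing interval (tolerance 10⁻¹⁰ on log δ). β's significance comes from
an F test with 1 and n − p degrees of freedom. With K = I the model
provably reduces to ordinary least squares; the tests assert agreement with
the closed-form OLS p to 10⁻⁶ (observed ~10⁻¹⁴). Missing dosages are
mean-imputed for the scan only; constant-dosage markers are skipped with
NaN p.

## Segregation classes and heterogamety

Alleles are oriented per marker so *b* is the rarer allele among all called
genotypes (tie → ALT). With carrier(b) frequencies c_F, c_M and hom-b
frequencies h_F, h_M:

- `w_strict`: c_M = 0 and c_F ≥ 0.5 — b confined to W haplotypes (not all
  females need carry it: several W haplotypes can segregate);
- `w_loose`: c_M ≤ τ_m (0.05) and c_F − c_M ≥ τ_Δ (0.3) — rare male
  carriers, compatible with occasional Z–W recombination or genotyping
  error (the two are not distinguished);
- `z_poly`: h_M ≥ τ_z (0.1) and h_F ≤ τ_m — the polymorphism lives on the
  Z, so only the homogametic sex can be hom-b;
- otherwise `ambiguous`.

The thresholds are package choices (the qualitative categories
"entirely/almost entirely female-exclusive" need numbers) and are all
exposed in `SegThresholds`. Heterogamety is a majority vote: a marker votes
female-heterogametic if its profile falls in a diagnostic class as
observed, male-heterogametic if the sex-swapped profile does; support is
the winning vote fraction. No likelihood model comparison between ZW and XY
is attempted. A detection limit is inherent to `z_poly`: the male hom-b
frequency is q², so Z-polymorphisms with q ≲ √τ_z ≈ 0.32 are genuinely
unclassifiable and fall to `ambiguous`.

"Textbook" reference markers (for the dosage diagnostics) require 100 %
call rate, MAF > 0.05 and a pooled-sexes Hardy–Weinberg chi-square
(1 d.f., expectations from observed allele frequencies) with p > 0.05.

## Dosage diagnostics

Sex-level total-depth summaries include **all** accessions, called or not —
a collapsed paralog can push an accession outside the callable range, and
dropping it would bias exactly the markers of interest. Genotype-
conditional allele-depth summaries can only use called accessions, and
additionally only cells with total depth ≥ `depth_floor` (default 10, twice
the calling threshold). The floor removes a real estimator bias: near the
calling threshold, heterozygotes whose binomial read split happens to be
all one allele are miscalled homozygous; these leaked cells concentrate at
low depth, drag the (small) minor-homozygote class mean down and fake
compensation violations. Conditioning both classes on the same floor
cancels out of the het/hom ratio (both expectations scale by
E[d | d ≥ floor]).

Diagnostics per marker, all thresholds in `DosageParams`:

- **Compensation**: for each allele with ≥ n_min (5) heterozygotes and
  same-allele homozygotes, ratio = mean het allele depth / mean hom allele
  depth. `dose_compensated` ⇔ every testable ratio ∈ 0.5 ± δ (δ = 0.15).
  `compensation_violated` additionally requires a one-sided Welch test to
  place the het mean beyond the *nearest band edge* at p < 0.01 — testing
  against the edge rather than 0.5 means sampling noise around a true ratio
  of ½ cannot trigger a violation regardless of how many markers are
  screened.
- **Sex depth ratio**: F/M mean total depth; `ratio_elevated` needs
  ratio ≥ 2 *and* Welch p < 0.01 on per-accession totals (depths are
  overdispersed; the guard suppresses small-n noise). A zero male mean is
  reported as `male_null` instead of a ratio.
- **Extra copies**: estimate = ratio − 1 (males carry one locus), floored
  at 0, with a seeded 200-resample bootstrap percentile interval over
  accessions. The estimate is scale-invariant in sequencing depth.
- **Paralog suspects**: compensation violated, or ratio elevated, or male
  null, or mean total depth a > 3 s.d. outlier against the textbook-marker
  depth distribution (skipped when no textbook set exists). Reasons are
  recorded per marker.

## Scaffold anchoring and copy model

A scaffold's chromosome is the strict majority (> 50 %) chromosome among
its map-marker hits passing e-value < 10⁻¹⁰; plurality or tie → NA, since
ambiguous scaffolds should stay unanchored. The center position is the
median cM of supporting hits — a single representative position robust to
outlier hits; the choice of median over mean is a package decision. W/Z
sub-labels ("Chr15W", "15Z") collapse to the chromosome number for conflict
detection only and are kept verbatim in reports.

Tag copy counting exposes its e-value threshold and an inclusive/strict
flag, and reports per-scaffold breakdowns (scaffolds with > 1 hit are
tandem-like). The combined copy-model verdict calls
`female_specific_multicopy` when the reference shows > 1 copy, the depth
ratio is elevated, and the extra-copy estimate is ≥ 1 but does not exceed
(n_copies − 1) + 1. The reference copy count is treated as an *upper*
bound, not a two-sided target: the reference assembly is female-derived and
assembled copies need not all recruit reads to the marker, so a depth
estimate below n_copies − 1 is still consistent evidence.

## The simulator

`simulate_population` emulates a wild dioecious association panel: sexes
drawn Bernoulli(female_fraction) (default 162/265 ≈ 0.61), optional
discrete subpopulations whose allele frequencies are Balding–Nichols
perturbations of a common frequency (the `fst_like_divergence` parameter is
the beta-model F), autosomal genotypes in Hardy–Weinberg proportions within
subpopulation, W-strict/W-partial/Z-polymorphic markers placed on the sex
chromosome, and collapsed-paralog tags: a base locus monomorphic for the
common allele in everyone plus `extra_w_copies` hemizygous W loci
contributing rare-allele reads in carriers, all superimposed onto one
emitted marker.

Read depth per **locus copy** is negative binomial with mean `mean_depth`
(default 20 reads — GBS-like coverage comfortably above the calling
threshold) and size `depth_dispersion` (default 10; at the depth of a
typical high-coverage reference marker, ~60 reads, this reproduces a
standard deviation of ~20, matching empirically reported overdispersion;
size → ∞ recovers Poisson). The depth law is a modelling choice — GBS
pipelines report only empirical means and s.d. A diploid single locus is
one draw split binomially between alleles by dosage; each hemizygous W copy
is an independent tag locus with its own full draw, so a paralog tag's
expected total depth is (1 + k)·mean_depth in carriers versus mean_depth in
non-carriers — the signal the dosage module estimates. Per-read miscalls
flip alleles symmetrically at `error_rate` (default 0.01); whole cells are
masked at `missing_rate` (default 0.05). Identical configs (including seed)
are bitwise reproducible.

Deliberately not modelled: recombination maps and pedigree structure,
sequence-level tag content, variable copy number among carrier females
(k is fixed per marker; depth-based estimates then have a single truth to
recover), depth variation between loci (all loci share one mean, which
makes the textbook depth-outlier rule *more* sensitive than on real data),
and unknown-sex accessions beyond random injection. Consequently, passing
tests demonstrate correctness of the estimators under the stated data model
— overdispersed counts, read error, missingness, structure — but not
robustness to locus-specific depth effects, allele-specific mapping bias or
batch effects present in real GBS data.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` use desk-scale designs chosen to
match the population they emulate where sizes matter (n = 265 accessions,
61/39 sex split) and 1,000–2,000-marker scans elsewhere: large enough that
binomial tolerances are meaningful, small enough to run in minutes. Every
stochastic stage takes an explicit seed; the acceptance script derives
independent sub-seeds from its `--seed` via `numpy.random.SeedSequence`.
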