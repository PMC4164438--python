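# Methods

This note documents the models implemented in `hapselect`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical/design decisions a maintainer would
want to know.

## Data model

Haplotypes are stored as an `n_hap × n_var` int8 matrix polarized to
0 = ancestral / 1 = derived (−1 = missing), over variants with strictly
increasing 1-based positions. Polarization happens at read time: the VCF
reader uses a per-record ancestral-allele INFO annotation (key
configurable, default `AA`, case-insensitive) and flips records whose
ancestral allele is the ALT; records that are unphased, multi-allelic, or
lack a usable annotation are skipped and reported. Missing alleles are
excluded from every frequency denominator; haplotypes with in-block
missingness are dropped (not imputed) from spectra and, per examined
interval, from EHH carrier sets. The recombination map is a monotone
piecewise-linear cumulative map (position bp, rate cM/Mb, cumulative cM);
queries outside the map span clamp to the boundary value by default
(HapMap maps are sparse at the edges and the blocks of interest are
interior), with a strict mode that raises instead.

## F_ST and the outlier rule

Three standard two-population estimators are provided. Hudson
(1 − H_w/H_b) and Nei G_ST use plain heterozygosities, so both are exactly
0 at equal sample frequencies; Weir–Cockerham is the sample-size-corrected
variance-components estimator and is slightly negative (≈ −1/(n−1)) there,
which is reported as computed (truncation at 0 is an option, off by
default). Published candidate-SNP F_ST values rarely state their
estimator; re-deriving them from printed frequencies with different
estimators spans a wide range, so no attempt is made to match any specific
published table value and every result carries its estimator name.
Outlier calling is purely empirical: percentile = 100 · #{background <
value}/|background| (ties rank below, matching the "higher than the 95th
percentile" convention), significant iff percentile > 95. The background
distribution of common-SNP F_ST values is a user input. The MAF screen
pools chromosomes across the requested populations (not an average of
per-population frequencies) and passes only on a strict MAF > threshold
(default 0.30).

## EHH, iHH and uiHS

EHH at target x for a core allele is the probability that two random
carriers are identical over the contiguous SNP interval [core..x]:
Σ C(eᵢ,2)/C(c,2) over identity-group sizes eᵢ. Profiles walk outward one
SNP at a time and stop at the matrix edge or when EHH drops below a
truncation threshold (default 0.05, the convention of the iHS literature;
points below threshold are excluded). By construction the profile is
monotone non-increasing outward on complete data. The walk is implemented
as an incremental partition refinement (numba-jitted); a direct
per-interval implementation (`ehh_at`) serves as the reference and the
test suite requires exact agreement between the two on random matrices.

iHH integrates the profile by trapezoid against genetic distance when a
map is supplied, else against physical distance; both sides of the core
are summed and no gap penalty is applied for sparse intervals.
`uiHS = ln(iHH_ancestral/iHH_derived)`; a zero area or a side with fewer
than two points makes the statistic undetermined (reported as such, the
analogue of "N.D." entries in candidate tables).

Significance uses a locus-matched neutral null rather than genome-wide
standardization: replicates are simulated with the same sample size,
number of segregating sites and recombination parameter (and optionally a
bottleneck demography), the replicate core is the simulated SNP nearest
the observed core's derived frequency (among SNPs with ≥2 carriers of
each allele), and p = (1 + #{|null| ≥ |observed|})/(1 + n_reps).

Two properties of unstandardized iHS are worth stating explicitly:

* Its neutral null is **not** centred at zero. Conditional on frequency,
  the derived allele is younger and its carriers form a clade, so
  iHH_derived exceeds iHH_ancestral on average (empirically E[uiHS] ≈ −0.3
  to −0.5 at core frequency 0.4–0.5). This is precisely why genome scans
  standardize iHS within frequency bins; the empirical-null comparison
  used here absorbs the shift instead, and the type-I error of the test is
  calibrated (≈5% at α = 0.05 in the acceptance suite).
* uiHS values are therefore **not comparable** to standardized iHS scores
  from genome scans; only their sign convention agrees (negative =
  selected derived allele).

When only the block itself is simulated or genotyped, iHH of a strongly
swept allele is truncated at the matrix edge, compressing |uiHS|; the
sweep-power test simulates a region wider than the swept block (600 kb at
the same SNP density and per-bp recombination rate) for that reason, as a
real scan has flanking markers.

## The haplotype-decay allele-age clock

After a sweep lifts a founder haplotype to high frequency, each carrier
chromosome independently loses founder identity by recombination
(probability r per generation — the block's genetic length in Morgans) or
mutation (probability μ per generation — the ascertained regional rate),
modelled as competing Poisson processes, so the intact fraction after G
generations is P = e^{−G(r+μ)} and G = −ln(P)/(r+μ). The observable proxy
for P is P′: within the block's derived-carrier haplotype spectrum, the
frequency share of the most frequent derived-carrying haplotype, which is
taken to be the founding (ancestral) haplotype; a tie for most frequent is
broken lexicographically and flagged with a warning. No correction is
applied for ongoing allele-frequency change (P′ is used as P directly).

Defaults, with units:

| parameter | default | meaning |
|---|---|---|
| per-base mutation rate | 1.1 × 10⁻⁸ /bp/generation | haploid rate |
| ascertainment probability | 10⁻³ | chance a true polymorphism entered the SNP panel; order-of-magnitude, configurable |
| region length | block bp span | multiplies to the regional μ (151 kb → μ = 1.66 × 10⁻⁶) |
| generation time | 25 y | converts G to years |

G is reported both as a real number and rounded to the nearest integer;
years are additionally rounded to two significant figures, the precision
at which such ages are meaningfully quoted. Block boundaries are
user-supplied SNP ids or column indices (automatic LD-block detection is
out of scope — published block bounds are typically read off an LD-plot
tool whose confidence-interval procedure is not reproducible from text).
No analytic confidence interval exists for this estimator; an optional
bootstrap over haplotype rows is provided as an extension and labelled as
such.

## Association stage

Group summaries use the n−1 SD and SEM = SD/√n; empty genotype classes
are absent rather than zero-filled, and a singleton group has an
undefined SD. Pooling of two summaries is exact (weighted mean;
within+between sum-of-squares with n−1 denominator), so pooled summaries
equal summaries of concatenated raw data to machine precision — this is
what the homozygote-vs-carrier comparisons are built from. The two-sample
test from summary statistics defaults to Welch: back-computing the
published homozygote-vs-carrier insulin comparison from its group
means/SDs/ns reproduces the reported p = 0.005 under Welch but not under
the pooled-variance Student test (≈0.025), despite the original table's
"Student's t-test" label; both variants are available and reported.
Comparisons follow the dominance grouping (each homozygote class vs the
pooled union of the other two). HWE is a plain Pearson χ² with 1 df and no
continuity correction. The additive model is OLS of phenotype on derived
allele count. No multiple-testing correction is applied by default
(two-sided α = 0.05 per comparison, as in the emulated analysis); a
Bonferroni report is available on the results object.

## Synthetic-data generators

All generators are deterministic under a seed (`numpy.random.default_rng`
seed trees; child seeds < 2³¹).

**Neutral haplotypes with fixed S.** A genealogy is sampled (built-in
Kingman sampler when ρ = 0 with constant size — only one marginal tree is
needed and this path is ~5× faster, which matters for the 201,000
simulations of the calibration experiment; msprime otherwise, with
recombination rate ρ/(4·Ne·L) and optionally the bottleneck demography
N1→N2 at T2, exponential growth to N3 from T1), then exactly S mutations
are placed with probability proportional to branch length × genomic span;
the root state is ancestral, so every column is polymorphic and polarized.
Fixed-S conditioning reproduces the neutral 1/i frequency-spectrum shape
only approximately: the per-mutation class probability is the expectation
of the per-tree ratio L_i/L_total, not the ratio of expectations, which
over-weights singletons by a few percent. The SFS test therefore bounds
the total-variation distance to the 1/i law (< 0.04) rather than applying
an exact goodness-of-fit test, which would (correctly) reject at large
replicate counts. The bottleneck parameters are not defaulted — no
published values exist for the emulated analysis — and must be supplied.

**Copy-and-erode sweeps.** A random background haplotype is copied onto
`round(freq × n)` rows; each copy accumulates Poisson(G*·r) recombination
break-ins (uniform breakpoint; the segment on the side of the breakpoint
away from the core is replaced by a random background haplotype) and
Poisson(G*·μ) in-block flips; the inserted core column carries the derived
allele on exactly the swept rows. Because the decay clock assumes every
event destroys founder identity, a break-in whose donor is identical to
the current haplotype over the spliced segment is redrawn (capped at 100
attempts): without this, ~30% of break-ins are invisible on realistic
backgrounds and recovered ages are biased low by the same amount. With
it, the age estimator recovers G* = 300 with ≈ −4% bias over 50 seeds.
What this generator does not emulate: selection dynamics during the rise
(the founder jumps instantaneously to its target frequency), ongoing
frequency change during erosion, gene conversion, and back-migration of
eroded haplotypes to the founder state (possible but negligible at the
rates used).

**Forward decay oracle.** Per-lineage first-event times under independent
Poisson processes with rates r and μ; returns the fraction intact at G,
with expectation e^{−G(r+μ)} and binomial Monte-Carlo error — the
independent check that the clock's forward law matches its inversion.

**Cohorts.** Genotypes are drawn at Hardy–Weinberg proportions for the
given derived-allele frequency (or with exact per-genotype counts when a
fixed design is wanted); each hormone is drawn per genotype class from a
normal truncated at zero (concentrations cannot be negative, and the
emulated group SDs are large relative to their means, so untruncated
normals would produce impossible values); missingness is independent per
subject and assay. Truncation shifts group means slightly upward relative
to the nominal parameters (≈ +1–2% at the default parameterizations);
round-trip tests compare against the truncated-normal mean. The packaged
parameterizations are the study conditions of the emulated cohort: 131
subjects, derived frequency 0.331, per-genotype hormone means/SDs as
published, 7% per-assay missingness emulating failed assays (observed
assayed ns ≈ 119–125 of 131), and a fixed 54/50/15 design for the
GIP-at-rs7754840 experiments. What the cohort generator does not emulate:
covariate structure (age, BMI), between-hormone correlation within
subject, assay floor/ceiling effects, and genotyping error — so passing
association tests demonstrate correctness of the statistics under the
generative model, not robustness to those real-data features.

## Problem sizes used in the test suite

Chosen as the package's own desk-scale defaults: the iHS type-I
calibration runs 1,000 trials against 200-replicate nulls at the emulated
panel size (120 haplotypes, 70 segregating sites); sweep-age recovery
averages 50 seeds at 180 chromosomes; association calibration uses 1,000
null cohorts and 400 powered cohorts; the decay-law check uses 10,000
lineages. The full suite completes in about five minutes on one CPU.

## Known limitations

* The allele-age estimator inherits the decay model's assumptions:
  star-like genealogy of carriers after the sweep, constant r and μ, and
  P′ as an unbiased stand-in for P. Ages are order-of-magnitude estimates;
  the two-significant-figure rounding reflects that.
* F_ST outlier significance is purely empirical and depends entirely on
  the user-supplied background distribution.
* uiHS is unstandardized by design (no genome-wide data is assumed); see
  above for the consequences.
* The VCF reader handles biallelic SNPs only; no liftover, phasing or
  imputation is provided.
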