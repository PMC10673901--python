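# Methods

## The synthetic study system

All analyses are exercised on data from a hierarchical Balding–Nichols
generator (`popdiv.simulate`). For each SNP an ancestral frequency p₀ is
drawn (default uniform on (0.05, 0.95)); a stratum frequency is drawn from
Beta(p₀(1−F_s)/F_s, (1−p₀)(1−F_s)/F_s) so that E[p] = p₀ and
Var(p) = F_s·p₀(1−p₀); population frequencies drift from their stratum
likewise with F_pop. F = 0 copies the parent frequency exactly. Genotypes
are Hardy–Weinberg draws. Translocated populations are generated
mechanistically, not statistically: binomial sampling of 2·n_founders gene
copies from the source, then g generations of binomial drift at 2·Ne copies.
The Balding–Nichols form was chosen over coalescent simulation because every
estimator's target is then available in closed form (e.g. the Hudson
ratio-of-expectations F_ST between two populations with drifts F₁, F₂
from their shared pool is (F₁+F₂)/2, with nested drift combining as
F_tot = F_s + (1−F_s)·F_pop); a coalescent generator could be added but is
not needed for any property tested here.

The default system (`default_config`) has 3 strata and 12 populations —
three mainland-like populations (F ≈ 0.05–0.10), drifted islands
(F ≈ 0.35–0.6) and three translocations founded with 100–160 individuals,
sizes 8–30 — chosen so pairwise F_ST spans roughly 0.005–0.6, the
strong-drift regime of long-isolated island systems. Loci are 125 bp RAD
loci with 1 SNP and 20 invariant sites each; invariant sites carry the same
depth/missingness model as SNPs so all-sites denominators behave like real
all-sites VCFs. (Real ddRAD datasets have a much larger invariant:variant
ratio, ~150:1; 20:1 keeps desk-scale runtimes while preserving every
denominator effect, so simulated all-sites diversities are ~7× larger than
typical empirical per-site values. Tests compare against the generator's own
latent values, never against empirical magnitudes.)

Artifacts: total depth per genotype is negative-binomial (default mean 20,
dispersion 5); heterozygote allelic depths are Binomial(depth, ½).
Missingness is missing-at-random given per-individual and per-site
propensities (individual effects Gamma with mean 0.4·rate; half of sites
dropout-free, the rest Exponential with mean 1.2·rate, overall expectation
equal to the configured rate, default 5%). The structure matters: with
uniform missingness a 100%-call-rate subset is empty at realistic sample
sizes, whereas concentrating dropout in a minority of samples and loci —
as in real RAD data — leaves one, which the quadratic-entropy cascade
requires. Technical replicates duplicate a genotype vector and flip calls at
the genotype error rate; full-sib pairs are Mendelian draws from two
simulated parents.

What the generator does **not** emulate: linkage beyond one-SNP-per-locus,
selection, mutation during drift, sex chromosomes, batch effects, and
reference/allele-dropout bias correlated with divergence. Passing tests
therefore demonstrate estimator correctness under drift and sampling noise,
not robustness to those real-data pathologies.

## Filtering cascade

Fixed order: site presence → max-H_O → one SNP per locus → allelic depth →
iterative call rate → MAC → replicate reproducibility → kinship. Boundary
semantics: H_O removal is strictly greater than 0.70; MAC keeps exactly 3;
all-sites depth bounds (5, 100) are inclusive (VCFtools semantics); mean
allelic depth must strictly exceed 2.5. The allele-balance screen is the
relative difference of mean ref vs alt depth over heterozygous genotypes,
|r−a|/max(r,a), removing at ≥ 0.80 — scale-free and symmetric; other
definitions of a "coverage difference" exist, so the ratio used is logged in
every report. The iterative call-rate schedule defaults to (0.5, 0.7, final)
on both axes and then re-applies the final thresholds until both hold
jointly; a one-shot filter at the final thresholds can retain a different
set, so the report logs each round.

Kinship is the allele-sharing moment estimator on dosages: pairwise matching
M from half-dosages, β̂ = (M − M̄)/(1 − M̄) with M̄ the mean off-diagonal
matching, which makes β̂ average exactly zero over pairs and puts full sibs
near 0.25. Because the centring is relative to the input sample, estimating
it across a strongly structured dataset makes every within-population pair
of a drifted population look related (we observed more than half of all
individuals flagged on the default system); the cascade therefore estimates
β̂ within each population and prunes greedily (highest above-threshold
degree first, ties to lower call rate) until no pair exceeds 0.25. The
pruning is deterministic and near-minimal (verified against minimal vertex
covers on toys).

## Diversity

H_O is Σ het / Σ typed over the chosen site set; H_E is the per-site
unbiased gene diversity ĥ = k/(k−1)(1 − Σp²) averaged over sites; π is
pairwise differences over C(k, 2). ĥ and π are algebraically identical per
site (both equal 2·c_ref·c_alt/(k(k−1))); computing both and asserting the
identity to 10⁻¹² guards the two independent code paths. Both variant-only
and all-sites denominators are reported, because per-site diversity is only
comparable across populations on the all-sites scale. Per-population
"independent recall" subsets a population to individuals with < 10% missing
data, demands complete genotyping across them, and re-classes sites
monomorphic within the subset as invariant — emulating an independent
per-population variant call.

Allelic richness is Hurlbert rarefaction per locus,
Σ_a [1 − C(N−N_a, g)/C(N, g)], at g = the smallest per-population typed-copy
minimum by default (computed with log-gamma for stability). Private-allele
standardization is seeded Monte-Carlo subsampling to n individuals per
population (default n = 6, 100 reps); note that subsampling can raise as
well as lower a population's private count (dropping another population's
copies of a shared allele mints a spurious private), so raw and standardized
counts are both reported and no ordering between them is assumed.

## Differentiation

All windowed statistics aggregate as ratio-of-sums (difference counts and
comparison counts summed over sites before division), which makes window
concatenation exact and handles missing data without per-site weighting
artifacts; windows are half-open [start, start+10kb) in 1-based coordinates.
D_XY counts cross-population allele-copy pairs; invariant sites enter the
denominator. F_ST offers WC84 variance components (default; window estimate
Σa/Σ(a+b+c); sites need ≥ 2 typed individuals per population) and the
Hudson/Bhatia estimator (Σ(Hb−Hw)/ΣHb with unbiased within-heterozygosity);
the two agree within 0.03 on balanced designs across F ∈ {0.05, 0.2, 0.5}.
A window with no informative site reports NaN, never 0. Note that
D_XY(A, duplicate-of-A) equals the *plug-in* (with-replacement) diversity
2pq of A, not the unbiased π — cross-copy comparisons pair each allele copy
with itself — and the tests assert that exact identity.

Isolation by distance: Mantel correlation of F_ST/(1−F_ST) with great-circle
distance (haversine), log-transformed by default (the two-dimensional
expectation); permutation p-value (#{r_perm ≥ r_obs} + 1)/(perms + 1) with
simultaneous row/column shuffles, seeded. Raw distance is available since
the choice is not always documented in field studies.

## Quadratic-entropy cascade

Squared genetic distance d²_ij = (1/L)Σ_l (x_il − x_jl)²/2 on complete-data
dosages (the codominant AMOVA convention): this embeds individuals in
Euclidean space, so with size weights every among-group component is
non-negative and the decomposition is the classical ANOVA identity (δ and β
equal twice the weighted squared centroid dispersions, which the tests use
as an oracle). Q of a set is the mean d² over ordered member pairs
(self-pairs zero). δ and β are defined as remainders, so additivity is exact
by construction under either weight mode; `size` (member counts) is the
default, `equal` is reported for comparison because the reference
implementation's standardization convention is not public and neither mode
is privileged a priori. Homogeneity uses Bartlett's statistic on components
treated as variances with df = member count − 1 per group (stratum totals −1
for the σ test); the arithmetic matches `scipy.stats.bartlett` exactly when
fed the corresponding sample variances.

## Metapopulation contributions

H_S = Σ w_i h_i (per-locus mean 1 − Σp²); D_G = Σ_ij w_i w_j d_ij with Nei
minimum distance and d_ii = 0; then H_T = H_S + D_G equals the gene
diversity of the w-pooled frequencies — an identity asserted to 10⁻¹² on
random tables. A_S is mean alleles per locus; D_A averages one-way allele
absences over ordered pairs including self-pairs, which makes
A_T = A_S + D_A exactly the mean pairwise-union allele count (enumeration
oracle in the tests). Loci are restricted to those typed in every population
so pooling identities hold exactly. Weights default to equal — the n = 6
subsample protocol equalizes sizes anyway — with size weights available.
Leave-one-out contributions are 100·(X_all − X_−k)/X_all with renormalized
weights (positive = diversity lost on removal); percentages are relative to
the component's own full-metapopulation value, with absolute deltas retained
alongside.

Optimal pool contributions maximize, over the weight simplex, either pooled
expected heterozygosity (concave) or the expected number of distinct alleles
among 2 × 1000 pool gene copies, Σ_a [1 − (1 − p̄_a)^2000] per locus (also
concave; the raw allele-union objective is degenerate because any positive
weight covers a population's whole allele set). Both are solved with SLSQP
under simplex constraints from multiple seeded starts with analytic
gradients, and verified against a 0.01-step simplex grid on small instances;
convergence tolerance 10⁻¹⁰.

## Allele-coverage prioritization

Features are (locus, allele) pairs observed in a population's subsample of
n = 6 individuals (both alleles of variant sites plus invariant-site
alleles, so a fixed-everywhere allele counts toward the total, matching the
"total number of alleles" convention); populations are unit-cost planning
units. The exact solver enumerates all C(P, k) subsets (P ≤ 25 enforced;
P is small in this domain, so an ILP backend is unnecessary); the greedy
solver carries the usual (1 − 1/e) guarantee and is checked against exact on
random instances. Ties break to the lexicographically smallest population-id
tuple so configuration tallies are reproducible. The protocol rebuilds the
feature matrix per iteration (default 100) with fresh subsamples and solves
exactly for every k, reporting per-k mean/min/max coverage proportions and
configuration tallies.

## Problem sizes and determinism

Everything is seeded through `numpy.random.default_rng`; identical seeds
give byte-identical outputs, and the pipeline manifest (parameters, seed,
input digests) suffices to re-run a pipeline exactly. Default analysis
sizes — 1500 loci, ~190 individuals, 100 prioritization iterations, 999
Mantel permutations — run the whole numbered workflow in about a minute;
recovery tests use 5000 SNPs with n = 50 per population, where the
genome-wide F_ST sampling error is well inside the ±0.03 assertion bands.
The acceptance script estimates the Mantel type-I rate from 500 null
replicates (standard error ≈ 0.010 at the nominal 0.05).

## Known limitations

Biallelic SNPs only (multi-allelic sites are skipped on read, with a count);
no phasing, imputation, sex chromosomes or BCF. The kinship estimator is a
moment estimator — low-coverage genotype uncertainty is not propagated.
Bartlett's test treats Q components as normal-theory variances; its p-values
on strongly non-normal dosage distances are screening-level only.
Contribution percentages depend on the weight convention, and the
among-population terms of the `equal` weight mode can be negative when
sizes are very unequal.
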