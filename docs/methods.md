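# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `ssrpg`, and what the synthetic-data tests do and
do not establish about real data.

## Data model

A `GenotypeMatrix` holds codominant diploid calls: per accession and
locus an unordered pair of positive integer allele codes (in practice
fragment sizes in bp) or a missing pair. Missingness is pair-level: a
half-missing input call (one allele read, one zero) is promoted to a
fully missing pair with a warning, because every downstream statistic
counts per-locus sample sizes N in whole individuals. Allele codes are
opaque — no size binning or stutter correction is attempted; allele
calling is upstream of this package.

Two interchange dialects are supported: a GenAlEx-style codominant CSV
(three header lines — counts, titles, population names — then one row
per individual with two columns per locus, `0` missing) and the
STRUCTURE flat format (two rows per individual, one allele per locus
per row, `-9` missing). GenAlEx serialization orders individuals by
population block, the only layout the dialect can express; STRUCTURE
round-trips preserve individual order and the population partition
(labels are recoded to `pop1..popK`).

## Synthetic data: what it emulates

The generator follows the Balding–Nichols construction: per locus an
ancestral frequency vector p (symmetric Dirichlet(1) unless supplied),
and per population a draw from Dirichlet(p·(1−F)/F), which has the
closed-form marginal Var(p_k) = F·p(1−p). The differentiation
parameter F therefore *is* the expected Fst, which is what makes
parameter-recovery tests meaningful. Genotypes are Hardy–Weinberg
draws within populations; missingness is MCAR per call.

`study_like_dataset` reproduces the emulated study's design constants:
416 accessions in populations of 374/16/26, the published 16-locus
panel with per-locus allele counts summing to 160, F = 0.04, and a
missing-call rate of 0.003, which keeps expected per-locus N in the
published 410–416 band. Where the publication is internally
inconsistent (one table lists the largest population as 375, another as
374) the germplasm-source listing (374) is followed.

What the simulator does *not* emulate — and therefore what passing
tests do not establish about real collections: inbreeding and null
alleles (simulated genotypes are HWE within populations, so simulated
AMOVA puts ~0% among individuals where the real collection shows ~13%,
and simulated Ho ≈ He where real SSR data often show heterozygote
deficit), mutation processes (no stepwise-mutation size structure),
linkage, clinal or admixed geography, and informative missingness.
Realized allele counts can fall below the nominal Na in small
populations; the generator deliberately does not resample to force
them.

## Diversity statistics

Frequencies are computed from non-missing calls only; a locus with zero
scored individuals propagates NaN (an explicit undefined marker), never
zero. He is the plain Nei gene diversity 1−Σp² — the headline column of
the standard toolchain — with the unbiased 2N/(2N−1) variant available
as an optional column. PIC uses the Botstein form, computed via the
identity Σ_{i<j}2p_i²p_j² = (Σp²)²−Σp⁴ and verified against explicit
double loops in the tests. Table means are unweighted arithmetic means
over loci; the per-population summary's Total row is an unweighted mean
over populations, mirroring the conventions of the published tables.

## F-statistics and AMOVA

Per locus, Hi/Hs are unweighted means over populations of observed and
expected heterozygosity, and Ht is computed from the unweighted mean of
the population frequency vectors (Nei-style; the size-weighted variant
is a flag, and with population sizes as skewed as 374/16/26 the choice
is consequential). Mean Nm over loci is the mean of per-locus Nm
values, not Nm evaluated at the mean Fst — the two differ because
0.25(1−F)/F is convex; the former is what the standard tool's mean row
reports. Degenerate cases carry explicit markers: Fis is NaN at Hs = 0
and Nm is +inf at Fst = 0.

AMOVA treats each allele copy as an indicator vector and sums the
nested ANOVA decomposition over loci and alleles, on the
half-squared-distance scale of the codominant convention (a
heterozygous individual-locus call contributes 0.5 to the
within-individual SS); this reproduces the SS magnitudes the standard
tool prints, and percentages are scale-invariant regardless. Degrees
of freedom are driven by the total individual count (k−1, N−k, N;
total 2N−1) while SS uses locus-wise complete cases, so sporadic
missing calls do not disturb the bookkeeping. Negative variance
components are truncated to zero for the percentage column with the
raw values retained. Permutation p-values are not computed by default
(the emulated analysis reported none).

## Distance, clustering and ordination

Nei's (1972) standard distance D = −ln(J_xy/√(J_x J_y)) sums the gene
identities over loci before taking the ratio; loci unscored in either
unit are excluded pairwise. For individual-level trees the genotype is
treated as a frequency vector (0/0.5/1); the shared-allele distance
ships as an alternative since the original tool offers several
individual-level options and the publication names only "Nei's
distance". When two units share no alleles, J_xy = 0 and D is capped at
10 (a documented constant) so clustering stays finite; pairs sharing no
scored loci are NaN and must be imputed or capped before clustering.

UPGMA is size-weighted average linkage with merge heights d/2, so
cophenetic distances reproduce average-linkage distances (verified
against scipy's implementation on tie-free inputs). Exact distance
ties are broken on the lexicographically smallest leaf-label pair,
making the tree — and its Newick serialization — fully deterministic.
Cutting the k−1 highest merges yields k clusters, with ids assigned in
leaf order.

PCoA is classical scaling: Gower double-centering of −½d², symmetric
eigendecomposition, coordinates scaled by √eigenvalue. Negative
eigenvalues (non-Euclidean input) are reported but excluded from
coordinates and variance percentages; each axis's sign is fixed so its
largest-magnitude loading is positive. On Euclidean input the
reconstruction is exact to 1e-9, and coordinates match scikit-bio's
PCoA up to sign.

## Admixture model and ΔK

The Gibbs sampler alternates allele-copy origins z ∝ q_ik·p_kl(a),
cluster frequencies P ~ Dirichlet(λ + counts) with λ = 1, and
ancestries Q ~ Dirichlet(α + counts). α is fixed rather than sampled;
the default is 1.0, and recovery analyses on strongly structured
simulated data use α = 0.1 — with a fixed symmetric α = 1 the posterior
mean Q is visibly shrunk toward 1/K even when assignment is perfect,
whereas a small α mirrors the concentration the adaptive reference
tool infers for such data. The model probability reported for model
choice is lnPD = mean(lnL) − var(lnL)/2 over the recorded post-burn-in
trace, an approximation mirroring the reference tool's statistic.

Chain defaults are desk-scale: 2,000 burn-in + 8,000 total iterations,
thinning 10 (the emulated study's 10,000/100,000 settings are accepted
via configuration). On the two-population recovery benchmark the
posterior is stable well below these lengths; the tests verify that
doubling burn-in moves posterior mean Q by < 0.05.

Evanno's table uses L′(K) = L̄(K)−L̄(K−1), |L″(K)| = |L′(K+1)−L′(K)|,
ΔK = |L″|/sd(L(K)); endpoints have no ΔK, a zero sd yields an infinity
marker, and a flat ΔK profile flags the choice as ambiguous rather than
silently picking an endpoint. Replicate label switching is handled by
greedy correlation matching of Q columns against the first replicate.

## Core collection

"Contribution to He" is realized literally as leave-one-out
recomputation: remove the accession, recompute set-level allele
frequencies, take the mean He over loci. The implementation maintains
incremental allele counts so the full 416-accession ranking runs in
O(N²·L). Ties are broken by ascending accession id, making the
removal order deterministic. Candidate cores are nested tails of the
removal order with sizes round(p·N) (half-up); the default grid is the
study's ten ratios 50%…5%.

Greedy backward elimination is not guaranteed optimal. On instances
shaped like the study's marker panel (16 loci, 4–8 alleles) it reaches
≥ 0.99 of the exhaustive optimum, which is the contract the tests
assert; on degenerate instances (very few loci) the shortfall can reach
~4%, a property of the algorithm itself.

Subset Na counts alleles actually observed in the subset, so Na
retention ≤ 100% is expected while frequency-based parameters routinely
exceed 100% — the published pattern. The core-vs-original comparison
uses the independent-samples t-test across per-locus values (the
convention of the statistics package the emulated study used). The
paired-by-locus variant is available but is far more sensitive: it
removes between-locus variance and detects the systematic upward He
shift that greedy selection induces, so it rejects where the
independent test — and the published analysis — do not.

## Pipeline and reproducibility

`ssrpg run config.toml` executes the stages in study order and writes a
CSV/Newick bundle; every output carries a header with the package
version, a hash of the scientifically relevant configuration, and the
seed. All randomness flows from explicit seeds (replicate seeds are
derived deterministically from the base seed), so reruns are
byte-identical. `scripts/acceptance.py` re-derives the headline
quantities from scratch at the full 416 × 16 design; its heavier
components (ten-seed Fst recovery, admixture recovery at n = 100 × 20
loci, a three-population ΔK scan at n = 120 × 15 loci with 3 replicates
per K) are sized to finish in well under a minute while leaving the
recovery signals far from their thresholds.

## Known limitations

- No rarefaction for allelic richness; Na comparisons across very
  different sample sizes are biased toward the larger sample.
- No HWE exact tests, null-allele correction, or Weir–Cockerham θ;
  the F-statistics are the Nei-style decomposition only.
- The admixture sampler has no correlated-frequencies prior, no
  linkage model and no location prior; α is fixed per run.
- AMOVA supports exactly the three-level hierarchy; a single
  population is rejected with a pointer to two-level analysis.
- The Nei-distance cap (D = 10) makes disjoint-allele pairs
  commensurable but is arbitrary; trees containing capped entries
  should be read qualitatively near those tips.
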