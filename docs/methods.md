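# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `epistage`, in the spirit of the methods
documentation of packages like statsmodels or msprime. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A dataset is an N×M matrix of genotype codes 0/1/2 (minor-allele counts;
−1 marks a missing call) with a binary phenotype (1 = case, 0 = control).
For PLINK text input the minor allele is determined per SNP over all
samples; ties are broken toward the lexicographically later allele so the
coding is deterministic. The genotype TSV dialect stores codes directly.

Joint-genotype counting has two exact backends. The bitwise backend stores,
per SNP and per phenotype class, three packed bit masks (one per genotype
code); a k-locus contingency cell is the popcount of the AND of k masks.
A missing genotype sets no bit, so samples missing at any of the k queried
SNPs drop out of that table (listwise per table — margins stay consistent
without imputation; how missing calls should enter the pair statistic is
genuinely open, and this is the package's choice). The dense backend
one-hot encodes genotypes and obtains whole batches of tables as matrix
products (all pairs against one SNP, or a (K−1)-locus prefix against all
later SNPs); missing genotypes one-hot to the zero row, so both backends
agree exactly, which the property tests assert. The batch backend exists
purely for speed: the all-pairs scan and the exhaustive K-subset
enumeration are GEMM-bound instead of Python-loop-bound.

## Quality control

Filters run in a fixed order, each on the data surviving the previous
step: sample call rate (≥ 0.98), SNP call rate (≥ 0.95), Hardy–Weinberg
equilibrium in controls (p ≥ 10⁻⁴), minor-allele frequency (≥ 0.1). The
HWE test is the 1-df chi-squared goodness of fit at the sample allele
frequency (not an exact test), matching the chi-squared toolkit used
everywhere else; monomorphic SNPs get p = 1 by convention and are left to
the MAF filter. The removal report lists entity, rule, observed value and
threshold for every exclusion.

## Pairwise screening

Every pair is tested on its 9×2 table with df fixed at 8. Rows with zero
margin are skipped in the summation while the df stays 3^k − 1, so
statistics remain comparable across tables with empty genotype
combinations. The two-threshold scheme retains pairs above the critical
value at α′ = ωα with α = α₀/C(M,2); pairs above the critical value at α
are labelled significant, the rest of the retained set intermediate. ω
trades candidate-set size against runtime; the default ω = 10⁴ targets
genome-scale M where ωα ≪ α₀. For small M, ωα can exceed α₀ (or even 1),
so α′ is capped at α₀: the intermediate band never admits pairs that fail
the nominal uncorrected level. The cap keeps the critical value well
defined and preserves the monotonicity of the candidate set in ω.

Strong-main-effect flagging uses the single-locus 3×2 test (df 2) at the
Bonferroni level α₀/M — M single-locus tests are performed, so this is the
natural correction. Pairs in the retained set containing at least one
flagged SNP are re-tested with the likelihood-ratio deviance; a pair is
discarded iff its deviance p-value is strictly greater than α′. Pairs with
no flagged SNP pass through untouched, and when no SNP is flagged the LRT
stage is skipped entirely.

## Logistic likelihood-ratio filter

The deviance D = 2(ln L̂_F − ln L̂_M) compares a full model — intercept,
two genotype indicators per SNP (codes 1 and 2 versus baseline 0), and the
four pairwise indicator products; nine parameters — with a reduced model
holding only the indicators of the flagged SNP(s). The nominal df are
therefore 4 (both flagged: 9 − 5) or 6 (one flagged: 9 − 3). Categorical
coding is used because only it is consistent with these df; a single
numeric slope per SNP would give df 1–3. Indicator columns for genotype
levels absent from the analyzed samples are pruned from both models, the
df reduced accordingly and the pruned levels recorded in the result.

Maximum likelihood is computed by Newton–Raphson on the binomial
log-likelihood: convergence when the log-likelihood improves by < 10⁻⁸,
at most 50 iterations. Complete separation (diverging coefficient norm or
a singular Hessian) switches on a 10⁻⁶ ridge on the Hessian, reported in
the fit metadata. These tolerances are robustness choices, not statements
about the statistic. The test suite checks the fits against an independent
iteratively-reweighted-least-squares implementation (statsmodels) to 10⁻⁶
and verifies that the deviance p-values are calibrated (rejection rate
near 0.05) on data generated under the reduced model.

## Stage-2 search

With W candidate pairs, W < 2×10³ dispatches to exhaustive search, larger
W to ant-colony optimization; the user can force either branch.

*Exhaustive*: all SNPs of all candidates are merged into one set S and
every K-subset of S is tested at df 3^K − 1; subsets with p < α₀/C(M,K)
are reported in ascending p order. Note the merge is global — the
strategy can report triples whose three pairs came from different
candidates.

*ACO*: pheromone starts at τ₀ = 100 for every candidate. Each ant selects
d distinct candidates (d = 2 for K = 3) by roulette with probability
∝ τ^δ η^β (δ = β = η = 1 by default, i.e. pure pheromone); selection is
exact successive sampling without replacement, vectorized across ants for
d = 2 by a cdf-adjustment trick. The union of the selected pairs is scored
by its χ²; three-SNP unions are scaled by f_s = 2 because the critical
value at df 80 is roughly twice that at df 26 and unscaled three-SNP
merges would otherwise lose every comparison against four-SNP ones.
Evaporation applies to *all* candidates each iteration (τ ← (1 − ρ)τ);
evaporating only selected pairs would freeze never-selected pheromone and
defeat exploration decay. Each selected pair then gains Δτ = 0.01 × the
ant's (scaled) fitness, accumulating over ants. A global list of the
top_t = 100 distinct unions by fitness is maintained across iterations;
after the last iteration every K-subset of every stored union is tested
and the Bonferroni-significant ones reported, deduplicated. Defaults
follow W: n_ants = 0.1 W clamped to [500, 5000], MaxIter = 0.1 W,
ρ ∈ [0.01, 0.1] with 0.05 used in the simulation studies. The whole search
is reproducible given the config seed; the reported set is by construction
a subset of what exhaustive search would report on the same candidates.

## Disease-model simulator

A model is a penetrance table f over the 3^k joint genotypes of k disease
loci with HWE genotype weights at the loci's MAFs. Derived quantities —
prevalence P(D) = E[f], per-locus marginal penetrances, marginal effect
sizes λ = odds(P_Aa)/odds(P_AA) − 1, and heritability
h² = Var(f)/(P(D)(1 − P(D))) on the penetrance (dichotomous) scale — are
always recomputed from the table, so calibration can be verified by
round-trip.

* `multiplicative3`: f = min(a(1+θ)^(g₁g₂g₃), 1). The baseline a is solved
  by 1-d root-finding so the (saturating) table hits the target prevalence
  (default 0.01) at each θ, and θ by an outer root-find so each locus' λ
  hits its target. Saturation at 1 is part of the model — at low MAF the
  required θ is large and the top table cells reach penetrance 1.
* `threshold3`: f = min(a(1+θ), 1) when every locus carries ≥ 1 minor
  allele, else a; same two-level calibration.
* `pure3`: at MAF 0.5 define t(g) = +1 for homozygotes, −1 for
  heterozygotes — a zero-mean ±1 variable under HWE. The table is
  f = P + B(t₁t₂ + t₁t₃ + t₂t₃) + A t₁t₂t₃ with 3B² + A² = h²·P(1−P),
  splitting the variance 50/50 between the pairwise and the three-way
  terms. Every single-locus marginal penetrance equals P exactly (all
  λ = 0 — the defining property of a no-marginal-effect model), while
  two-locus marginals stay informative, so the pairwise screening stage
  has a route to the loci; a fully pure parity construction would hide the
  triple from any pair-based screen and describes a different (and for a
  pair-screening method, adversarial) regime. Prevalence defaults to the
  smallest feasible value for the requested h² (the two-valued bound
  h² ≤ P/(1−P) applies; e.g. h² = 0.4 forces P ≥ 0.286) and an explicit
  prevalence is validated against the feasible range.
* `custom_table`: any user table, validated and annotated the same way.

Datasets are drawn by sampling disease-locus haplotypes at HWE, assigning
case status with probability f(g), and accumulating until exactly n_a
cases and n_u controls are collected (a draw budget guards against
near-zero prevalence). Background SNPs are independent HWE draws with MAFs
uniform in [0.05, 0.5]; disease columns are placed at random positions and
recorded in a truth record. With LD r² < 1 the genotyped columns are
markers coupled to the latent disease haplotypes allele-by-allele: the
marker allele copies the disease allele with probability 1 − ε and is an
independent frequency-matched draw with probability ε = 1 − √r², giving
haplotype correlation √r² and hence squared correlation r² in closed form.

Power is the fraction of replicates in which the detector's reported sets
contain the *exact* planted locus tuple (marker tuple when r² < 1); no
partial credit. Per-replicate RNGs derive deterministically from the
config seed.

What the simulator does *not* emulate: linkage disequilibrium among
background SNPs, population structure, genotyping error, missingness
patterns, haplotype effects. Passing power tests therefore demonstrate the
statistical machinery under idealized sampling, not robustness to the
confounders of real GWAS data.

## Problem sizes used in tests and the acceptance script

The simulation studies run at the sizes of the package's reference
experiments: pure three-locus power at h² = 0.4 with N = 400, M = 100 and
50 replicates; ACO recovery from 5×10³ candidates (3 planted + padded null
pairs over M = 150) across 20 seeded runs with n = 500 ants, ρ = 0.05,
MaxIter = 0.1 W; LRT null calibration with n = 2000 and 200 replicates;
whole-pipeline false-positive control on pure noise with M = 100,
N = 1000 and 100 replicates. These sizes are the package's reference
conditions and are chosen once.

## Known limitations

* The pairwise scan is O(M²) in time; the exhaustive stage is
  O(|S|^K) — both are meant for filtered or simulated panels (M up to a
  few thousand), not raw genome-wide matrices, which require the streaming
  retain-above-threshold contract but considerably more engineering.
* The logistic filter offers no covariate adjustment.
* Only autosomal biallelic SNPs are handled; PLINK binary and VCF input
  are out of scope.
* With very small samples the chi-squared approximation on 27+ cell tables
  is anti-conservative; no exact or permutation variant is provided.
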