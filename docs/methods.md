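# Methods

## Data model

A species' color at one life stage is a **pattern**: 1–4 RGB patches, each
with an ordinal **area category** (1: primary color covering >80% of the
animal; 2: primary shared with another primary, 30–50% each; 3: secondary,
10–30%; 4: secondary, <10%). Categories are mapped to weights at the
midpoints of those ranges — 0.85, 0.40, 0.20, 0.05 — and renormalized to sum
to 1 per pattern; the mapping is configurable. Every pattern must contain at
least one primary patch.

Two derived representations feed the statistics:

- the **6-D primary vector** (R₁,G₁,B₁,R₂,G₂,B₂): the two primary colors,
  ordered brightest (largest R+G+B) first; a single primary is duplicated.
  Brightness ties break lexicographically on (R,G,B) descending, so
  vectorization is deterministic and invariant to patch order. Patterns with
  more than two primaries (messy real tables) keep the two with the largest
  area weight, ties to the brighter patch, with a logged warning.
- the **weighted color distribution**: all patches with their normalized area
  weights, used by the area-weighted and earth-mover's metrics and by the
  background-distance score.

## Palette quantization

RGB values hand-sampled from unstandardized photographs carry illumination
noise. All measurements are pooled and quantized by k-means (default k = 20,
20 restarts, fixed seed), then centers whose channel sum falls below a
darkness threshold (default 90) are merged into their count-weighted mean —
separate "blacks" from different photographs are redundant. The merge is
idempotent. Downstream distances operate on the cluster-assigned ("snapped")
colors; ties in nearest-center assignment go to the lowest center index.
The darkness threshold doubles as the definition of a "bright" (non-dark)
patch in the warning-color analysis, so there is a single notion of dark.

## Distance metrics

- **A, Euclidean 6-D**: ‖v(a) − v(b)‖ on primary vectors. Cheap, primary
  colors only.
- **B, area-weighted**: Σᵢⱼ wᵢᵃwⱼᵇ‖cᵢᵃ − cⱼᵇ‖, the expected patch distance
  under independent draws from the two area-weight distributions. Uses all
  colors and their areas.
- **C, earth mover's distance**: the minimum-cost transport of one species'
  unit color mass onto the other's, ground cost Euclidean RGB. Solved as a
  transportation LP (HiGHS) to 1e-8; validated in the tests against exhaustive
  enumeration of basic feasible solutions on small instances. EMD ≤ B always
  (the optimal plan beats the independent coupling), and EMD satisfies the
  metric axioms on cluster-assigned patterns.

**Internal contrast** of a pattern defaults to the *maximum* pairwise patch
distance: a black + bright-yellow pattern is maximally contrasting no matter
how small the yellow patch, which is how high-contrast warning patterns are
judged in the field. An area-weighted mean aggregation is available.

**Background distance** scores a pattern against sets of natural green and
brown background colors: per sample s, Σᵢ wᵢ‖cᵢ − s‖. The default pools both
sets and averages ("average distance to natural backgrounds"); a
`min_per_background` mode takes the smaller of the two per-set means, the
conservative reading under which matching *either* background is crypsis.

## Phylogenetic signal

The multivariate K statistic generalizes the univariate signal ratio to p
traits (the implementation reduces exactly to univariate Blomberg's K at
p = 1, and equals 1 identically on a star phylogeny):

K = [tr(EᵀE) / tr(EᵀC⁻¹E)] ÷ [(tr C − N/(1ᵀC⁻¹1)) / (N−1)]

with C[i,j] the shared root-to-tip branch length of tips i and j, â the GLS
root-state estimate and E the tip residuals. C is inverted through a Cholesky
factor; posterior trees can contain zero-length branches that make C exactly
singular, in which case an escalating ridge (1e-10 → 1e-6 of the mean
diagonal) is applied with a warning. The permutation test shuffles which
species' trait row sits on which tip; P = (1 + #{K_perm ≥ K_obs})/(n_perm+1)
with 999 permutations by default, so P is never exactly zero. Monte-Carlo
calibration (tests): mean K over 200 Brownian simulations on a 64-tip tree
lies in [0.9, 1.1], and tip-shuffling lowers K in ≥95% of paired replicates.

Across a posterior sample, K is computed per tree on the species common to
all datasets and the tree (trees with fewer than 3 usable tips are skipped
with a warning), and signal differences between datasets are summarized as
the fraction of trees on which each dataset's K exceeds the reference's.

## Stage coupling and diversity

- **Mantel**: Pearson r between the upper triangles of two distance matrices
  after label alignment; the null jointly permutes one matrix's rows and
  columns. Default 10,000 permutations, one-tailed "greater" (the hypothesis
  is positive coupling); two-sided available. Because a permutation leaves
  the entry multiset unchanged, the triangle mean and norm are precomputed
  once, making the loop a single masked inner product per draw. N ≥ 3 is
  required for r; in practice N ≥ 4 is needed for a meaningful test.
- **D**: mean of all N(N−1)/2 between-species distances under a chosen
  metric, optionally per family (groups of <2 species are skipped).
- **D_dif test**: observed D_cat − D_adult against a null permuting stage
  identity. The default scheme swaps each species' caterpillar and adult
  patterns with probability ½, preserving the species pairing and per-species
  color content while breaking stage identity; `free_relabel` repartitions
  the pooled 2N patterns into two arbitrary groups of N. Both one-sided
  +1-corrected P values are reported, ties counting as extreme on both sides
  (hence p_lower + p_upper ≥ 1). Default 1000 permutations (100 recommended
  for metric B, whose matrix is the most expensive). All 2N patterns'
  pairwise distances are computed once; each permutation is then just a
  submatrix mean.
- **PCA of the 6-D vectors** is provided for visualization only; no statistic
  consumes the scores.

## Strategy classification

Background-distance scores are cut into cryptic / ambiguous / contrasting.
Automatic thresholds place the two cut points at thirds of the observed score
*range* (equal-width bands); in the pipeline the bands are computed on the
two stages' pooled scores — one histogram, one set of cut points — so the
stages are classified on a common scale (a per-stage option exists via
explicit thresholds, which override the automatic rule and reproduce any
published split). Classification is monotone in score. Transition tables
cross-tabulate the 3×3 larval × adult categories over species classified at
both stages. For species contrasting at both stages, the **bright element**
(non-dark patch with the largest area weight, ties to the brighter) of each
stage is mapped to its palette cluster; the species "shares its warning
color" when both stages land in the same cluster — named colors are not
available, so shared cluster identity is the computable surrogate.

## PGLS over posterior trees

GLS with error covariance σ²C_λ, where C_λ keeps the diagonal of C and
scales off-diagonal entries by λ (Pagel's transform — the same one-line
definition the generator uses). λ defaults to 1 (pure Brownian, matching the
common default of the standard comparative-regression tools); bounded ML
estimation of λ on [0,1] is available and recommended whenever the response
carries substantial non-phylogenetic variance: with λ fixed at 1, sister
tips joined by near-zero branches are treated as nearly exact replicates and
receive enormous weight, so iid noise at those tips produces wildly inflated
t statistics (verified in development: a contrast regression with true t ≈ 0
showed |t| > 14 under fixed λ = 1 and t ≈ 0 under ML λ). σ̂² uses the
residual degrees of freedom N − k; two-sided P from the t distribution.
Binary predictors are fit with a 0/1 encoding by the same machinery.

Across a tree sample, the fit is repeated per tree (species re-matched each
time) and each parameter summarized by its **HPD interval**: the shortest
window of the sorted per-tree values containing ⌈prob·n⌉ of them, ties going
to the earliest window (deterministic; no kernel smoothing).

## Synthetic data generator

The generator emulates the statistical structure of a two-stage color study
on a continent-wide butterfly radiation:

- **Tree**: pure-birth with n tips (default 98, the number of species with
  phylogenetic information in the emulated study; birth rate 1). The
  simulator stops exactly at the n-th birth, so the clock is run forward by
  the Exp(n·λ) waiting time to the next speciation, keeping the tree
  ultrametric and its covariance nonsingular.
- **Posterior sample**: the same topology with every branch multiplied by an
  independent lognormal(0, sd) factor (default sd 0.1, default 2500 trees to
  match the emulated scale; analyses accept any subsample).
- **Colors**: 6-D latent traits evolve by Brownian motion on λ-transformed
  covariances (λ_cat = 1, λ_adult = 0.3 by default); the adult latent is
  ρ·(larval) + √(1−ρ²)·(independent replicate), ρ = 0 by default — the
  decoupled regime. Latents are standardized per column, mapped to mean
  127.5 with per-stage spread (sd 20 for caterpillars, 60 for adults: the 3×
  adult color-space expansion), clamped to [0,255] and rounded; clamping
  beyond 1% of values is logged (at the default adult spread ~3% of adult
  values clamp — the price of a 3× spread inside a bounded gamut). Species
  get 1 or 2 primary patches (P(two) = 0.7) plus 0–2 random-colored
  secondary patches, counts drawn independently per stage (sharing them
  would couple the stages' internal contrasts even at ρ = 0).
- **Body size**: log larval size = Brownian baseline (sd 0.3) +
  0.5·standardized larval contrast + N(0, 0.1); adult size adds the same
  noise once more, giving the tight larval–adult size correlation real data
  show.
- **Backgrounds**: 10 greens and 10 browns drawn uniformly from fixed natural
  channel ranges.

One seed drives everything; identical configs give byte-identical bundles on
disk. What the generator does **not** emulate: UV reflectance, within-species
variation, non-Brownian evolution (OU, jumps), correlated patch colors within
a pattern, and observation error in area categories — passing tests therefore
validate the statistical machinery, not the realism of any particular
biological claim.

## Numerical and design notes

- Permutation P values always use the +1 correction and count ties as
  extreme; all tests are deterministic given a seed. The pipeline fans one
  global seed out to per-stage seeds by hashing (seed, stage-name), so
  stages are reproducible in isolation.
- On a star phylogeny both K ratio terms equal the tip depth, so K = 1 to
  machine precision — a useful exactness check.
- The end-to-end problem sizes used by the test suite and the acceptance
  script (64–98 species, 20–250 trees, 199–10,000 permutations) were chosen
  so the full validation completes in minutes; all statistics stabilize well
  below the emulated 2500-tree scale.

## Known limitations

- **Mantel anticonservatism under residual signal.** When *both* stages
  retain phylogenetic signal (λ_adult > 0), the two distance matrices
  correlate through shared ancestry even when the stage traits are generated
  independently (ρ = 0): expected distances in both stages are monotone in
  patristic distance. The plain Mantel permutation null does not account for
  this, and rejects at ~12–16% instead of 5% under the default decoupled
  configuration; the clean null requires one stage without tree structure
  (λ_adult = 0 gives ~6%). Consequently, a significant Mantel result on real
  data is weaker evidence of stage coupling than its P value suggests. No
  partial-Mantel or phylogenetically corrected variant is provided.
- Fixed λ = 1 PGLS is fragile at zero-length branches (see above); use ML λ
  for responses with measurement noise.
- Strategy thresholds depend on the observed score range, so adding species
  can relabel existing ones; explicit thresholds avoid this.
- Raw RGB is not a perceptual color space and carries no receiver model; all
  distances underestimate differences a UV-sensitive predator would see.
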