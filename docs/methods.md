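# Methods

This note documents the models, definitions, numerical choices, and known
limitations behind `concordscape`. Everything quantitative stated here is
computed by the test suite or the analysis drivers; nothing is asserted that
the code does not check.

## Concordance factors

For an internal branch of a binary reference tree, the four subtrees
incident to its two endpoints define a *quadripartition* (S1, S2 | S3, S4);
the branch's bipartition is (S1 ∪ S2) | (S3 ∪ S4).

- **gCF.** A gene tree is *decisive* for the branch iff it contains at least
  one taxon from each of S1..S4. A decisive tree is *concordant* iff its
  split set, restricted to the taxa it shares with the reference, contains
  the branch's induced bipartition. gCF = 100 · concordant / decisive. When
  no gene tree is decisive the factor is undefined and reported as `NA`,
  never 0.
- **sCF.** Quartets are drawn with one taxon per quadripartition set,
  uniformly with replacement (`n_quartets = 100` by default; when the number
  of distinct combinations is at most `n_quartets`, all combinations are
  enumerated instead). For a quartet ordered (s1-member, s2-member,
  s3-member, s4-member), a site is decisive iff all four characters are
  unambiguous nucleotides and the pattern is a clean binary xxyy, xyxy, or
  xyyx; the first of these supports the branch. sCF is the unweighted mean
  over quartets of 100 · s1/(s1+s2+s3); quartets with no decisive site are
  dropped from the mean rather than scored 0. Sites containing gaps or
  ambiguity codes (all collapsed to N on input) are never decisive.

The decisiveness definitions follow the concordance-factor literature; the
quartet sample size and the unweighted mean are package defaults recorded in
every report together with the RNG seed. Each branch consumes an independent
child stream of a single seed sequence, so reports are byte-stable and
independent of evaluation order.

## The landscape scan

For k ingroup clades plus an outgroup, all (2k−3)!! rooted binary
arrangements of the clade labels are enumerated by recursive leaf insertion
and canonicalized (children ordered by smallest descendant label), giving
deterministic two-letter IDs `aa`, `ab`, … in canonical order (an optional
seeded shuffle mimics arbitrary labeling). Each arrangement's k−2 internal
clade-level branches are expanded to full-taxon quadripartitions by pooling
clade members — clades are assumed monophyletic, so taxa substitute freely
within them. Per-arrangement means cover exactly these k−2 branches: the
ingroup/outgroup split and all within-clade branches are shared by every
arrangement and excluded. gCF depends only on a branch's bipartition, so it
is computed once per distinct clade-level bipartition (25 for k = 5) and
shared; sCF is recomputed per arrangement because the quadripartition
context and quartet draw differ.

Treespace is embedded by classical MDS (principal coordinates) on the
pairwise Robinson–Foulds matrix. Two conventions matter:

- Rooted trees are compared on their *rooted clade sets* (complementary
  clades kept distinct), so arrangements differing only in root placement
  are at positive distance and RF is a proper metric on the 105 skeletons.
  The collapsed, unordered-bipartition view is still what `bipartition_set`
  returns for generic use.
- Negative eigenvalues are truncated to zero and axis signs fixed by the
  largest-magnitude loading. The complete 105-arrangement set is highly
  symmetric and its spectrum has tied eigenvalues, so the leading *plane* is
  not unique — the embedding is reproducible for a fixed input order, and
  exactly order-invariant (up to reflection) only when eigenvalues are
  distinct.

Gene-level support labels (`arr1`/`arr2`/`arr3`/`uninformative`) classify
each gene by which pooled arrangement of a focal quadripartition its splits
contain. The conservation covariate is a transparent stand-in for
trimming-tool similarity scores: the mean over columns of the fraction of
identical pairs among rows with unambiguous nucleotides (in [0, 1]); class
comparisons use two-sided Mann–Whitney tests with Benjamini–Hochberg
correction, skipped with a warning for classes of fewer than two genes.

## Likelihood core, likelihood mapping, SOWH

The scoring model is JC69 by default (GTR without rate heterogeneity is
available); keeping the core this small makes every likelihood verifiable
against closed forms and exhaustive ancestral-state sums, which the tests
do. Felsenstein pruning runs over compressed site patterns with per-node
rescaling; gaps/N contribute partial likelihood 1. Branch lengths on a fixed
topology are optimized cyclically, one bounded scalar search per branch
(bounds [1e-8, 10], initialized at 0.1), sweeping until the log-likelihood
improves by less than 1e-6 or 100 sweeps; the ascent is monotone and a
convergence flag is returned.

Likelihood mapping scores the three arrangements of each quartet,
normalizes weights as exp(lnL_i − max lnL) (underflow-safe), and assigns a
basin (argmax) and one of seven regions by a dominance rule: corner i iff
p_i ≥ 2p_j and p_i ≥ 2p_k; else side ij iff p_i and p_j both ≥ 2p_k; else
center; ties resolve toward the lower-numbered region. The factor 2 is a
configurable convention — the original method partitions the simplex
geometrically and published counts should not be compared across rules
without checking this choice.

The SOWH test fits both topologies to the observed data, takes
Δ_obs = lnL(best) − lnL(null), simulates `n_reps` alignments (same site
count) under the fitted null tree, recomputes Δ per replicate the same way,
and reports the add-one p-value (1 + #{Δ_rep ≥ Δ_obs}) / (1 + n_reps), which
is never exactly zero. With 20 replicates the test can only reject at
α = 0.05 when no replicate reaches Δ_obs, so its nominal level is 1/21.

Two calibration facts, both measured by the suite, matter for
interpretation. First, the statistic and p-value accounting are exactly
exchangeable: when replicates are simulated from the *true* generating
parameters, the rejection rate at α = 0.05 is the nominal 1/21. Second, the
practical test plugs in *fitted* null parameters, and those absorb the
dataset's realized signal: on data simulated under a null tree with a
clearly positive internal branch, Δ_obs ranks mid-pack among its own
replicates essentially always (p concentrates near 0.5) and the test is
strongly conservative. Its size is attained at the least-favorable null
configuration — internal branch at the boundary (length → 0) — where the
rejection rate is within binomial noise of the nominal level; the
calibration test evaluates it there. In practice this means SOWH rejections
are trustworthy (the test does not over-reject anywhere on the null), while
non-rejections on strongly structured nulls are weak evidence.

## Discrete-trait layer

Species are classified from rearing-record counts: *generalist* iff two
substrates each exceed 1/4 of records or no substrate exceeds 2/3;
otherwise specialist in the unique substrate above 2/3; no records at all →
*unknown* (excluded from mapping). The Mk model (ER by default; SYM/ARD
available) is fitted by maximizing the pruning likelihood over
log-parameterized rates with a flat root prior; because the surface
saturates for fast rates (tip data become iid at stationarity and the
gradient vanishes), optimization starts from the best point of a coarse
log-spaced grid before L-BFGS-B refinement.

Stochastic maps are sampled exactly: node states root-to-tips from the
conditional distributions implied by the pruning partials, then each
branch's path conditional on its endpoint states by uniformization
(dominating rate μ = max |Q_ii|; the number of latent jumps is drawn from
its exact conditional series, interior states by forward–backward weights,
jump times as uniform order statistics; virtual self-jumps are collapsed).
Rejection sampling was deliberately avoided: uniformization has bounded
cost on short branches with unlikely endpoint pairs. Transition censuses
count state changes per branch, split terminal vs internal, accumulate a
from→to matrix, and report the pooled fraction of changes with the
generalist state as source or target. The max-posterior summary assigns each
node its most frequent sampled state (ties broken by state name) and flags
branches whose parent and child summaries differ. Per-map transition counts
and summary-tree change counts are different accountings and are reported
separately, not asserted equal.

## Synthetic data

The generator provides every stage's inputs with known truth:

- **MSC gene trees** via msprime: the species tree (ultrametric, branch
  lengths in coalescent units) becomes a demography with all population
  sizes 1 and haploid samples, so simulated times are already in coalescent
  units. The closed form P(concordant) = 1 − (2/3)e^(−T) for an internode of
  length T is the test oracle (checked at T ∈ {0.1, 0.5, 1, 2} against
  2,000 genes within 3 binomial SE).
- **Sequences**: iid sites evolved root-to-tips under the scoring model;
  branch lengths in substitutions/site (gene trees are scaled by a single
  global substitutions-per-coalescent-unit factor, 0.02 by default).
- **Traits**: forward Mk simulation recording the full history, so realized
  transition counts are known exactly.

The default fixture emulates a radiation-scale supermatrix: 24 taxa in five
ingroup clades (sizes 6, 2, 4, 5, 4) plus a 3-taxon outgroup; 200 genes ×
300 sites. Clade crowns sit at age 2.0 and radiation nodes at ages
[5.32, 5.42, 5.55, 5.7] with the root at 12.0, giving long clade stems
(stem-branch gCF above 85 — clean monophyly) and three short contentious
internodes of 0.38, 0.13, and 0.15 coalescent units whose branch gCFs land
in the 15–40 band with sCF near the chance line, the signature the package
exists to dissect. The ages were chosen so that, at 200 genes, the planted
arrangement reliably tops the mean-gCF landscape while its deep branches
remain genuinely contentious. The trait layer uses four states at ER rate
0.05 per coalescent unit (roughly a dozen realized transitions on this
tree), and rearing records are drawn so that classification recovers each
species' true state (specialists get occasional strays kept below the 1/4
trigger; generalists get two-way splits).

What the fixture does *not* emulate: missing data beyond optional uniform
taxon dropout (real occupancy is gene- and clade-structured), rate variation
across sites and genes, alignment error, introgression (discordance here is
purely coalescent), and model misfit (sequences are simulated under the
scoring model). Passing tests therefore certify the machinery — the
definitions, the estimators, the samplers and their calibration — not
robustness to the pathologies of real transcriptome data.

## Problem sizes and determinism

Test and benchmark sizes were picked to make each check statistically sharp
at desk scale: 2,000 genes for coalescent recovery (3 binomial SE), 50,000
sites for the sCF null (Monte-Carlo SE ≈ 0.1), 200 meta-replicates × 20
bootstrap replicates for SOWH calibration, a 200-tip balanced tree with
0.15-length edges for rate recovery (edge length chosen where Fisher
information about the rate is near its maximum — long edges saturate,
short ones carry no changes). Every stochastic routine takes a seed or
Generator; seed sequences are spawned per branch/gene/replicate so results
are independent of iteration order, and fixture bundles are byte-identical
across runs with the same seed.

## Known limitations

- JC69/GTR without Γ rate heterogeneity; empirical log-likelihood
  differences from tools fitting richer models are not comparable in
  magnitude.
- sCF uses the unweighted quartet mean; likelihood-weighted variants and the
  per-arrangement discordance factors (gDF/sDF) are not implemented.
- The seven-region likelihood-mapping rule is a dominance approximation to
  the original geometric partition.
- The MSC simulator assumes an ultrametric species tree and one haploid
  lineage per taxon; no migration or introgression.
- Rooted-RF treespace coordinates are unique only up to reflection, and only
  the leading plane is reported.
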