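# Methods

## Model

Units (population samples or diploid individuals) are tips of a rooted
binary tree whose root is the common ancestral population.  Every
non-root node `q` names the branch above it and carries a coancestry
parameter θ_q ∈ [0, 1].  Conditional on the parent frequency p_A at a
locus, the child frequency p_q satisfies

    E[p_q | p_A] = p_A,   Var[p_q | p_A] = θ_q p_A (1 − p_A),

with siblings conditionally uncorrelated given their parent.  θ
aggregates the effect of drift, migration, mutation and selection along
the branch; the tree is a best-fitting description of the covariance of
present-day allele frequencies, not necessarily a literal history.
Zero-length branches are allowed, so effectively multifurcating
structures are representable inside the binary search space.

Two F_ST functionals are defined on the fitted tree (see README for the
formulas): the correlation form FSTW aggregates θ over branches shared
by the two root-to-tip paths, and the mismatch form FSTH over the
non-shared branches.  They depend on disjoint parameter sets.  The
diagonal FSTW(k) is the divergence of a single unit from the root;
FSTH(k) ≡ 0.

## Estimation

The per-pair statistic S_kk′ (README) is a ratio of sums over loci;
its expectation under the model is ∏_{q∈R(kk′)}(1−θ_q).  Inference
minimizes the log least-squares objective ξ over β_q = log(1−θ_q) ≤ 0,
equivalently a non-negative least squares in γ = −β, solved by
`scipy.optimize.nnls` (Lawson–Hanson, exact).  All binary topologies on
K tips have 2(K−1) parameters, so ξ is comparable across topologies.

Topology search: (i) *clustering* — from the star tree, K−2 merge steps;
each step tries every pair of current root children (C(j,2) candidates
at child count j, O(K³) NNLS solves overall) and keeps the ξ-minimal
merge; (ii) *improvement* — tips are revisited in seeded random order;
for each tip every branch of the tip-removed tree (plus the original
position) is tried as a new attachment point and the ξ-minimal placement
kept.  Passes repeat until a pass changes nothing (cap 10; in practice
the first pass converges).  ξ never increases.

Every candidate is fitted by a cold NNLS solve.  Warm-starting from the
previous fit is a possible speed-up but is unnecessary at the problem
sizes here and is not implemented; cold solves keep every candidate fit
exactly reproducible.

## Numerical choices

- **Clipping.** The model expectation of S lies in (0, 1], but finite
  samples can give S = 0 (first unit fixed at every shared locus) or
  S slightly above 1.  Before taking logs, S is clipped to
  [`clip_eps`, 1] with `clip_eps = 1e−12`.  Pairs with ΣD = 0 (both
  units fixed everywhere) are undefined and their rows are dropped; the
  solve proceeds (with a warning) even if fewer rows than parameters
  remain.
- **Tie-breaking.** Candidate ξ values equal within relative 1e−12 are
  ties: the clustering phase keeps the lexicographically smallest label
  pair, the improvement phase keeps the current tree.  With a fixed seed
  the whole fit is bit-reproducible.
- **Missing data.** Every pairwise sum runs over loci observed in both
  members of the pair.  Because sample size may then vary across loci,
  the n_k/(n_k−1) factor is applied per locus inside ΣN_k, preserving
  per-locus unbiasedness of p̂(1−p̂)·n/(n−1).  (With complete data this
  reduces to the constant prefactor.)
- **Products and sums.** Products of (1−θ) are computed as
  exp(Σ log1p(−θ)) with θ = 1 short-circuited to 0; locus sums use
  numpy's pairwise summation, stable at genome scale.
- **Orientation.** All statistics use p(1−p) forms and are invariant to
  which allele is counted.  The VCF reader counts ALT copies; diallelic
  SNVs only.

## Simulator

`simulate_replicate` emulates independent-site evolution down the tree:
ancestral frequency p ~ beta(0.4, 0.4) (U-shaped: ~19% of sites outside
(0.01, 0.99), ~36% outside (0.05, 0.95)); each child frequency is drawn
from the unique beta distribution matching the conditional moments,
shapes a = p(1−θ)/θ and b = (1−p)(1−θ)/θ, with exact handling of θ ∈
{0, 1} and fixed parents; finally binomial gamete sampling at the tips.
Only SNV sites (pooled sample carries both alleles; no MAF threshold)
are retained.  Scenario presets S1–S6 fix (gametes, sites) =
(25, 10⁴), (10, 10⁴), (2, 10⁴), (25, 10³), (10, 10³), (10, 10²) on the
benchmark five-population tree (θ = 0.15 on the two branches below the
root, 0.10 on D, 0.05 elsewhere).

*Admixture variant*: before C's drift draw, its parent's frequency is
replaced by α·p₁ + (1−α)·p₃ — a deterministic frequency-level mixture.
Mixing individual alleles binomially instead would be indistinguishable
at the frequency level simulated here.  True FSTH values under admixture
come from a Monte-Carlo oracle: population frequencies only (no gamete
noise) at ≥10⁶ sites, plugged into the mismatch-probability definition
FSTH = 1 − (E[p_k(1−p_k)] + E[p_k′(1−p_k′)]) / (E[p_k(1−p_k′)] +
E[p_k′(1−p_k)]), with batch-means standard errors (10 batches).  At
α = 0 the oracle agrees with the closed form, at α = 1 with the closed
form on the rewired tree.

What the simulator does *not* emulate: linkage disequilibrium (sites are
independent), mutation, selection, inbreeding, varying sample sizes
across loci, genotyping error, or related individuals.  Passing tests
therefore validate the estimator under its own model assumptions; on
real data, LD reduces the effective number of independent loci and close
relatives violate the two-gamete-unit assumption.

## Evaluation

`run_scenario` scores both estimators over replicates: per-pair RMSE
against the exact closed-form truth (or the admixture oracle), never
against sample means; per-pair RMSE ratios (pairwise ÷ tree-based, >1
favours the tree); rooted-topology accuracy via clade-set equality; and
the estimate–truth Pearson correlation computed per replicate across the
10 pairs, then averaged (the alternative reading — pooling all
replicate-pair values — agrees to ~1e−3 at these settings).  Replicates
with undefined pairwise estimates are excluded and tallied; none occur
at the preset scenarios.

## Problem sizes and expected spread

The original study used 10⁴ replicates per scenario.  The acceptance
script and the study-scale tests use 2000 replicates for the RMSE and
efficiency-ratio quantities (Monte-Carlo SE of RMSE(AB)×10⁴ under S4
≈ 0.9; of the S3 mean ratio ≈ 0.01), 1000 for the admixture correlation
(SE ≈ 3e−4), 3000 for S6 topology accuracy (SE ≈ 0.85 points), and 20
replicates of 10⁴ sites for SNV percentages (SE ≈ 0.1 points).  A full
run of `scripts/acceptance.py` takes a few minutes on one core.

## Known limitations

- The greedy two-phase search can in principle return a local optimum of
  ξ; at desk scale the exhaustive-enumeration oracle (K = 5, 105
  topologies) confirms the global minimum is found on noiseless input.
  In the lowest-information scenario (S6, ~66 SNVs) recovery is the most
  sensitive to search minutiae such as tie-breaking and the handling of
  S > 1, which is why the topology-accuracy check carries the widest
  tolerance in the suite.
- FSTW between internal nodes is not exposed; only tip pairs (and tip
  diagonals) are reported.
- The admixture model is simulation-side only: inference always fits a
  tree, and under strong admixture no tree reproduces the true
  covariance (the efficiency advantage over pairwise estimation then
  disappears, though correlation with truth stays high).
- No LD modelling, no bootstrap support values, no locus-specific F_ST.
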