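# Methods

`rootedml` is a desk-scale maximum-likelihood phylogenetics engine. Its
distinguishing feature is first-class support for *nonreversible*
substitution models — the Lie Markov DNA family, the unrestricted 12-rate
DNA model (UNREST) and a fully general 380-rate amino-acid model (NONREV) —
together with the rooted-tree likelihood machinery these models require:
time-directed pruning, root search, and rooted-aware tree rearrangement.
Around that core it provides the standard reversible toolbox (GTR-class
models, empirical amino-acid matrices, discrete-gamma / invariant-site /
FreeRate heterogeneity), quartet likelihood mapping, NNI tree search,
fast branch supports (aLRT, SH-aLRT, aBayes), RELL-based topology tests
(SH, AU, ELW), phylogenetic-terrace detection and cost-ranked per-locus
scheduling.

## Substitution models

A model is an n-state continuous-time Markov generator Q with nonnegative
off-diagonal rates and zero row sums. Every constructor normalizes Q so the
expected substitution rate at stationarity is one, `-sum_i pi_i Q_ii = 1`;
branch lengths are therefore expected substitutions per site throughout.
Stationary frequencies of nonreversible models are obtained by a dense
least-squares solve of `pi Q = 0` with the simplex constraint appended
(n <= 20, so dense is exact to ~1e-12). Reversibility is detected by the
detailed-balance residual `max |pi_i Q_ij - pi_j Q_ji| < 1e-10`, so a
nonreversible parameterization that happens to satisfy detailed balance
(e.g. UNREST built from GTR rates) is correctly flagged reversible.

**GTR** takes 6 exchangeabilities (order AC, AG, AT, CG, CT, GT) and a
frequency vector; `Q_ij = s_ij pi_j`. **UNREST** takes 12 free rates in
row-major ACGT order; irreducibility is verified by strong connectivity of
the positive-rate digraph. **NONREV** generalizes this to 20 states (380
rates) and can be seeded from an empirical reversible matrix (LG, WAG, JTT,
shipped as PAML-dat text resources), in which case it starts on the
reversible submanifold. Empirical matrices and Jukes-Cantor are
fixed-parameter models: the optimizer never touches their rates.

### The Lie Markov catalogue

The catalogue enumerates the 99 named Lie Markov DNA models: 37 model
structures named `<dim>.<index><letter>`, of which 31 depend on the
distinguished base pairing (RY, WS or MK — purine/pyrimidine,
strong/weak, amino/keto) and therefore appear in three variants, while six
structures (1.1, 3.3a, 4.4a, 6.7a, 9.20b, 12.12) are pairing-independent:
31 x 3 + 6 = 99. Each entry carries a generator basis of 4x4 zero-row-sum
matrices; a model instance is a nonnegative combination of generators,
normalized, with stationary frequencies from the null-space solve.
Parameter vectors that would drive an off-diagonal rate negative are
rejected with an error naming the offending entry — never silently clamped,
because clamping corrupts optimization gradients.

Generator bases are exact for the structures with classical equivalents:
1.1 (the fully symmetric one-parameter model), RY2.2b (two-rate
transition/transversion), 3.3a (the three-pair-class symmetric model),
4.4a (target-frequency columns), 6.7a (the joint span of 3.3a and 4.4a),
6.6 (pair-swap symmetric rates), 9.20b (doubly stochastic generators,
spanned by permutation matrices minus identity), and 12.12 (= UNREST, one
generator per off-diagonal entry). For the remaining structures this
package ships its own deterministic pairing-adapted spanning sets of the
published dimensionality: the symmetric generator plus dim-1 single-entry
rays chosen by a fixed per-structure offset, which guarantees linear
independence, valid rate-matrix cones, irreducibility for positive
parameters, and three genuinely distinct pairing variants. The catalogue's
countable structure (names, dimensions, pairing multiplicities, the total
of 99) is exact; the generator coefficients of those remaining structures
are a documented stand-in for the published family tables, which are not
reproduced here. Analyses that depend on the precise constraint pattern of
a specific mid-family model should treat those entries accordingly.

### Rate heterogeneity

`discretize_rates(alpha, p_inv, k)` builds k equal-weight discrete-gamma
categories using the *mean* of each quantile slice, computed in closed form
via regularized incomplete gamma functions (for Gamma(a, rate a) the slice
mean between quantile cuts is an incomplete-gamma difference at shape a+1).
An optional zero-rate category of weight `p_inv` models invariant sites;
gamma rates are then rescaled by 1/(1-p_inv) so the overall mean rate is
exactly one. FreeRate models accept arbitrary increasing rate vectors with
free weights, renormalized to mean one; increasing order is enforced for
identifiability.

### Ascertainment bias

For variable-sites-only data the likelihood is conditioned on variability:
`lnL_corrected = sum_site lnL_site - n_sites * ln(1 - p_const)`, with
`p_const` the probability of a constant column computed by the same pruning
kernel on synthetic constant alignments. Alignments containing columns
compatible with a constant state are rejected (listing the 1-based
columns), as is the degenerate `p_const -> 1` case.

## Transition probabilities

`P(t) = exp(Qt)` is computed by two routes. The default eigen route
diagonalizes Q once per parameter setting (complex eigenvalues are expected
for nonreversible Q) and exponentiates the spectrum per branch; the
decomposition is cached keyed by a byte-fingerprint of Q. The matrix is
flagged *defective* — and the stable scaling-and-squaring route
(scipy's Pade implementation) used instead — when the eigenvector condition
estimate exceeds 1e8 or the relative reconstruction error exceeds 1e-8;
these thresholds are this package's choice, trading a cheap conservative
switch for the fast-but-occasionally-unstable eigen path. The imaginary
residue of the eigen route is checked (< 1e-10) before the real part is
taken; larger residues trigger the stable route. Entries more negative
than -1e-10 are an error (an algorithmic bug, not rounding); rounding-level
negatives are clamped to zero.

## Likelihoods on rooted and unrooted trees

Partial likelihoods have shape (patterns, rate categories, states) and are
propagated post-order. Rootedness is structural: a root of out-degree 2 is
a rooted tree, a basal trifurcation an unrooted one. Nonreversible models
demand a rooted tree (the likelihood is direction-dependent); reversible
models accept either, and the pulley principle (root-placement invariance)
is verified to 1e-8 in the test suite. Root frequencies default to the
model's stationary distribution — the parsimonious choice; a free-root
option was considered and rejected for the default because it adds n-1
parameters the data often cannot resolve at desk scale.

Underflow protection rescales a pattern's partial vector whenever its
maximum drops below 1e-80, accumulating per-subtree log factors; on a
2,000-taxon fixture the unscaled computation underflows to -inf while the
scaled one is finite. The safe mode used for taxon-rich alignments
(automatically above 2,000 sequences, or forced with `--safe`) rescales at
every internal node instead of on demand; both paths agree to better than
1e-6 where both run.

### Branch-length optimization

Each branch is optimized one-dimensionally with all others fixed, using
outside/inside conditional vectors so a single tree traversal per edge
makes each trial length an O(patterns) evaluation. The per-edge surface is
*not* reliably unimodal over the full admissible range [1e-6, 10]: it can
exhibit an interior optimum plus a long-branch saturation plateau, and a
naive bracketed search over the whole interval can converge to the plateau.
The optimizer therefore scans a 13-point logarithmic grid (augmented with
the current length) and refines the best bracket with bounded Brent
(xatol 1e-8). Sweeps repeat until the total lnL gain drops below 1e-4
(tighter, 1e-9, for the local pair-optimizations inside root search);
the lnL trace is non-decreasing by construction.

### Model-parameter optimization

Coordinate ascent: branch lengths, then Q parameters (L-BFGS-B on
log-rates, with the last rate fixed as the scale anchor; Lie Markov models
optimize raw cone coordinates with rejection-as-penalty), then rate
heterogeneity (bounded searches for alpha in [0.02, 100] on a log scale and
p_inv in [0, 0.95]), repeated until the round gain is below 1e-4 (at most
10 rounds; parameter-recovery experiments converge in 2-3). Steps that
fail to improve the likelihood are discarded, so the trace is monotone.

### Site-specific rates

Empirical-Bayes rates are posterior means over the fitted categories,
`sum_c r_c P(c | site)`; they necessarily lie within the category range.
ML rates replace the mixture by a per-site multiplier of all branch
lengths, found on a 64-point log grid over [1e-4, 100] and refined by
bounded search in the bracketing interval — the grid guards against the
multimodality of per-site surfaces. Reports are 1-based
`Site / Rate / Category` TSV.

### Root search

Candidates are branches within a configurable edge radius of the current
root branch (default 2, `--root-dist`; all branches on request). Each
candidate is rerooted at the edge midpoint and its two root-adjacent branch
lengths re-optimized to tight tolerance. Under a nonreversible model each
candidate additionally receives a short (two-sweep) full branch-length
optimization before comparison: rerooting reverses the time direction of
edges throughout the tree, so lengths carried over from another rooting
handicap candidates unevenly — without this step the handicap was measured
at hundreds of lnL units on 6-taxon replicates and root recovery degraded
visibly. Ties retain the incumbent; the winner gets a final full sweep.
With a strongly asymmetric UNREST model and 20 kb alignments the true root
branch of 6-taxon trees is recovered in 20/20 seeded replicates; under a
reversible model all candidates tie to within 1e-6, as the pulley principle
requires.

## Tree search

Starting trees come from randomized stepwise-addition parsimony (Fitch
scores via vectorized bitmask intersection DP; insertion order shuffled per
seed; ties to the lexicographically smallest canonical Newick) and from
neighbor joining on JC-corrected distances (Poisson-corrected for amino
acids; saturated corrections capped at 10). Hill climbing evaluates both
NNI rearrangements of every eligible internal branch with branch-length
re-optimization, applies the best non-conflicting set of strictly
improving moves (regions of influence must be disjoint subtrees; if the
joint application underperforms the best single move, the single move
wins), and repeats to a local optimum. *Fast* mode stops there. *Default*
mode adds 10 rounds of stochastic perturbation (random NNIs on about half
the internal branches) followed by hill climbing, keeping the best tree
seen — a desk-scale rendition of the explore/exploit balance of
production search heuristics, which live in cited prior work and are out
of scope here. In rooted trees the two root-adjacent branches are
NNI-ineligible; root placement belongs to root search. Constrained
searches discard any candidate (starting placement, NNI move or perturbed
tree) whose splits conflict with the constraint tree, so a violating tree
can never be emitted. `--runs N` performs N independently seeded searches
and reports them ranked by lnL. On 5-taxon instances with 1 kb of data the
default search matches the exhaustive 15-topology optimum in >= 18/20
seeded replicates.

## Quartet likelihood mapping

For each sampled quartet the three resolved topologies are scored by exact
ML over their five branch lengths, with substitution-model parameters
frozen at full-alignment estimates (the two-stage design keeps "exact ML
per quartet" a branch-length-only problem). The three log-likelihoods are
exp-normalized into barycentric posteriors and assigned to the classic
seven regions: corner i where `p_i >= 2/3` (resolved), the central
triangle where all `p_i > 1/6` (star-like), and three edge quadrilaterals
between them (pairwise conflict); boundary points go to the region with
the lexicographically smallest tag, and the corner-cut lines meet the
simplex edges at the 1/3 points, reproducing the standard geometry. All
quartets are evaluated when there are at most 10,000; otherwise 10,000 are
sampled without replacement (seeded). Cluster mode draws one taxon per
group for four groups, pairs within groups for two or three.

## Branch supports and topology tests

All resampling tests operate on per-site log-likelihoods expanded from the
pattern compression (resampling is over sites, not patterns) and share one
multinomial weight stream per replicate across trees, which the paired
RELL comparisons require.

* **aLRT**: `2(lnL_ML - lnL_second-best-NNI)` with local branch
  re-optimization; support `1 - p` under the 0.5*chi2_0 + 0.5*chi2_1
  mixture; a zero statistic maps to support 0 (the mixture's point mass).
* **SH-aLRT**: nonparametric version; RELL replicates of the three
  arrangements are centered by their expected totals and the support is
  the percentage of replicates where the observed statistic beats the
  centered null.
* **aBayes**: exp-normalized posterior of the ML arrangement under a
  uniform prior over the three.
* **SH**: centered replicate maxima; p-values are monotone non-increasing
  in the observed lnL deficit, and the ML tree's p-value is maximal.
* **ELW**: mean exp-normalized replicate weight; sums to one.
* **AU**: multiscale bootstrap over 10 scales (0.5 to 1.4), bootstrap
  proportions (ties split fractionally) mapped through the normal quantile
  and fitted as `z(r) = d sqrt(r) + c / sqrt(r)` by weighted least squares
  with binomial variance weights; `p = 1 - Phi(d - c)`. Trees never/always
  best at every scale get p = 0/1 with a degeneracy warning; fewer than
  two usable scales is an error.

The AU implementation is calibrated on a null of two fixed, equally wrong
resolutions (internal branch 0.03) of star-generated quartet data at
1,000 sites: the rejection rate at the 5% level is 5.5% over 200 replicate
datasets with 1,000 RELL replicates per scale. Two remarks on that
protocol: re-optimizing candidate branch lengths on star data collapses
both candidates onto the star (identical site likelihoods and no
rejections — the comparison becomes vacuous rather than boundary-null),
and alignments much shorter than ~1 kb leave the multiscale normal
approximation visibly anticonservative. Gene and gene-site resampling
schemes resample loci (and sites within drawn loci) under a partition map
covering every site exactly once.

## Missing data: terraces and per-locus scheduling

A species tree induces one tree per locus by dropping locus-absent taxa
(degree-2 suppression, branch lengths summed). Two trees lie on the same
terrace when every induced unrooted topology matches — compared via
canonical forms that reroot at the smallest leaf and sort children by
descendant labels, so the comparison is rooting-invariant. Detection is
pairwise over an explicit candidate set (final per-run trees), not full
terrace enumeration, which needs the dedicated machinery of the cited
literature; the user-facing behavior — report co-members and advise
gathering more data — is what pairwise checks deliver at desk scale.
Partial terraces are reported through the per-locus agreement vector.

Per-locus inference ranks loci by estimated cost — sequences x distinct
patterns x states, patterns counted on the locus's present taxa — and
assigns them to k workers by longest-processing-time greedy scheduling
(top k seed one worker each; every next job goes to the earliest-finishing
worker; ties by locus name). LPT's classical 4/3 - 1/(3k) makespan
guarantee is verified against brute-force optima on 1,000 random
instances. Scheduling decides order and assignment only; per-locus results
are identical for any k.

## Synthetic data

The simulator draws root states from the root frequencies, per-site rate
categories from the rate model, and child states through `P(t r)` along
each branch in depth-first preorder, with a documented RNG consumption
order (categories, then root states, then branch transitions) so every
fixture is reproducible from its seed. Missing data is injected only as
whole-taxon-per-locus dropout, matching the coverage model that terraces
assume. Random trees come in Yule, balanced and caterpillar shapes with
exponential branch lengths. The simulator produces i.i.d. sites without
indels, heterotachy, compositional drift or alignment error; passing
recovery tests therefore demonstrate correctness of the estimators under
the model, not robustness to real-data violations of it.

Default study conditions used by the verification suite: 8-taxon / 10 kb
GTR+G4 (alpha 0.5) simulations for parameter recovery (20 seeds;
exchangeabilities within 15% relative error, alpha within a factor two);
6-taxon / 20 kb strongly asymmetric UNREST for root recovery (20 seeds);
5-taxon / 1 kb for search optimality (20 seeds vs the exhaustive
15-topology optimum); 8-taxon trees with 0.5-substitution internal
branches for quartet mapping (>= 90% corner quartets). The acceptance
script (`scripts/acceptance.py`) recomputes the same quantities at
slightly reduced replicate counts (10 seeds for the two heaviest
recoveries, 100 null datasets for AU calibration) to keep a full from-
scratch run in the tens of minutes on one core; sizes are printed in its
JSON output.

## Numerical choices, ties, degenerate inputs

Branch lengths live in [1e-6, 10]; optimizer tolerance 1e-6 lnL for 1-D
searches, 1e-4 for full loops. All tie-breaks (search candidates, region
boundaries, scheduling, catalogue lookups) are lexicographic and therefore
deterministic; every stochastic component takes an explicit seed, and
per-run seeds are derived as base + index. Gaps, `?`, and `N`/`X` are
fully unknown characters (all-ones tip partials); IUPAC codes map to their
state subsets. Patterns compatible with a constant state are detected for
ascertainment checks by intersecting tip partial supports. Degenerate
requests fail loudly: empty taxon subsets, unrooted trees under
nonreversible models, reducible rate matrices, constant columns under ASC,
out-of-cone Lie Markov parameters.

## Known limitations

Terrace detection is pairwise, not enumerative. The default tree search is
a simplified stochastic hill-climb, not the full production heuristic of
the cited literature. Mid-family Lie Markov generator sets are
representative spans, not the published tables (see above). NONREV's 379
free parameters are optimizable in principle but impractically slow at
desk scale; the intended use seeds NONREV from an empirical matrix.
Per-locus scheduling simulates workers for determinism rather than running
processes in parallel; wall-clock parallelism is a non-goal.
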