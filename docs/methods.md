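# Methods

`cladediv` analyses dated, family-level phylogenies — ultrametric trees whose
tips are terminally unresolved clades (families) with known extant species
richness — to ask why species numbers differ so much between clades.  Its
stages mirror a standard comparative workflow: estimate richness, compute
net diversification rates, regress richness on clade age within age windows,
examine the rate–richness correlation against a permutation null, and locate
rate shifts with a stepwise birth-death model search.

## Richness from taxonomic evaluation counts

Checklists report, per family, accepted names (S_A), rejected synonyms (S_R)
and names awaiting evaluation (S_U).  Assuming unevaluated names are accepted
at the same rate as evaluated ones,

S = S_A + S_A·S_U / (S_A + S_R).

S is kept real-valued throughout; it is rounded to the nearest integer ≥ 1
only where a likelihood needs a count.  If S_A + S_R = 0 with S_U > 0 the
acceptance fraction is unestimable and the package raises rather than
guessing; such families need a direct published estimate (overrides always
win over counts).  The estimator is monotone (↑ in S_A and S_U, ↓ in S_R)
and bounded by S_A ≤ S ≤ S_A + S_U.  Simulation (`simulate_taxonomic_counts`)
shows the ratio-form bias is negligible at realistic family sizes (< 2% at
S = 1000 with 50% synonymy and 60% evaluation).

## Net diversification rates

For a clade of stem age t (My) and richness S, with relative extinction
ε = μ/λ held fixed,

r̂ = ln[S(1−ε) + ε] / t,

the Magallón–Sanderson stem-age method-of-moments estimator.  ε = 0 and
ε = 0.9 bracket plausible rates (ε > 0.9 would imply implausibly fast
turnover).  r̂ is exactly 0 for monotypic clades under every ε, monotone
non-increasing in ε, and satisfies r̂·t = ln[S(1−ε)+ε] identically.  Stem
ages are used exclusively; crown-age variants are out of scope.  Ages run
backward from the present in My; the root, having no subtending branch, is
assigned stem age equal to its crown age so the whole-tree clade can carry a
rate.

## Age-window regressions

The time-for-speciation hypothesis predicts a positive ln(S) ~ stem-age slope
among clades of comparable age.  Clades are binned into half-open 10-My
windows ([lo, lo+10), lo = 20…90 by default; younger clades are excluded to
match the reported analysis band, older-than-100-My clades because the tree
is node-poor and highly nested at depth).  Because nested clades are
non-independent (a descendant is by definition poorer than its ancestor),
each window is pruned so no two retained clades share taxa; the pruning runs
twice, keeping the older or the younger member of each nested pair.  On a
tree, taxon-set overlap is equivalent to ancestor–descendant containment, so
the overlap test is set intersection; processing order (by stem age, ties by
clade id) makes the result deterministic.  Each pruned window is fitted by
OLS (slope, two-sided slope p, R²); all window × variant p-values form one
Benjamini–Hochberg family, which is why identical adjusted values recur
across the two subtables.  Windows with n < 3 or zero age variance are
flagged unfit and excluded from the family.  Phylogenetic (PGLS-style)
regression is deliberately not used: the nested-pruning design addresses the
non-independence directly.

## Rate–richness correlation and its permutation null

ln(S) is regressed on r̂ across all clades.  Because r̂ = ln[S(1−ε)+ε]/t is a
deterministic function of S, this correlation is expected to be strong even
when richness carries no biological relation to age: permuting the richness
values across clades (ages fixed; permuting ages instead is identical in
distribution), recomputing r̂ and refitting yields R² values comparable to
the observed one.  `randomization_null` reports the observed R² and the
permuted distribution; replicate i draws from the i-th spawned child of a
`SeedSequence`, so results are bit-reproducible and independent of replicate
order.  The null is descriptive — it shows how much R² the functional
coupling alone buys — not a significance test.

How much it buys depends mainly on the spread of 1/t.  With richness spread
as published (mean ln S ≈ 5.9, max 12.82) the mean permuted R² is ≈ 0.5 when
clade ages span the 20–100 My analysis band, but drops to ≈ 0.2–0.3 if the
table also contains many very young (< 15 My) or very old clades, whose
1/t values dominate the variance of r̂.  The bundled
`seedplant_marginal_clade_table` therefore draws ages from the only per-clade
age distribution available in print (the per-window counts of the 20–100 My
regression table) and richness from the published moments (≈6% monotypic
mass plus a truncated normal on ln S); tables with broader, unpublished age
tails will sit lower.

## Birth-death likelihood with unresolved tips

Writing r = λ−μ, ε = μ/λ and D(t) = λ − μe^{−rt}:

* a lineage alive at age t survives to the present with probability r/D(t);
* conditional on survival it leaves N = S species with the geometric law
  P(S) = (1−β)β^{S−1}, β = λ(1−e^{−rt})/D(t) (for a pure-birth model this is
  β = 1−e^{−λt});
* a lineage at age a has exactly one reconstructed descendant at age c, all
  side branches extinct by the present, with probability
  g(a,c) = e^{−r(a−c)}·[D(c)/D(a)]².

The log-likelihood of a stem-rooted partition is the sum of log g over its
internal branches, log λ per branching event, and the *unconditioned*
richness term log[(r/D(s))·(1−β)β^{S−1}] per family tip of stem age s — the
tip term absorbs the entire pendant branch, which is the stem-conditioning
convention for unresolved clades.  For a fully resolved tree this reduces
algebraically to the classical product p₁(a)·∏λp₁(xᵢ) with
p₁(t) = r²e^{−rt}/D(t)², which the tests verify factor-by-factor.  The root
partition has no stem branch and its root node carries no λ factor (crown
conditioning); the model is not conditioned on survival.

Numerics: likelihoods are evaluated through `expm1`/`log1p` forms that stay
finite for rt from 10⁻⁸ to hundreds; S = 1 short-circuits the geometric term
so monotypic tips never produce 0·(−∞).  Pure-birth fits use a bounded
scalar search on log λ (λ ∈ [10⁻⁸, 10]); birth-death fits use L-BFGS-B on
(log r, ε) with ε ∈ [0, 1−10⁻⁶] from four starts spanning ε ∈ {0.05, 0.5,
0.9, 0.99}, seeded by the pure-birth optimum.  Fits pinned at the ε ceiling
or the r floor are flagged — very high fitted ε is itself a warning sign
that constant-rate assumptions are violated.  A birth-death fit can never be
reported worse than the pure-birth fit it nests (the ε = 0 edge is taken if
the optimizer does worse).

## Stepwise shift search

A single model is fitted to the whole tree; then, at each step, every branch
(internal or tip stem) is evaluated exhaustively as a break-point at which a
fresh model governs the branch and everything tipward of it (until a nested
break-point).  Only the two affected partitions are refitted; each partition
independently keeps the better of the allowed model kinds (pure-birth /
birth-death) by total AICc, with

AICc = −2·logL + 2k + 2k(k+1)/(n_obs − k − 1),

k = Σ model parameters + one per break location, n_obs = internal nodes +
family tips.  The best candidate is accepted while AICc keeps improving;
ties resolve to the first candidate in a fixed preorder, so the search is
fully deterministic.

**Stopping rule.**  Accepting any positive AICc improvement overfits
badly: the chosen break is the maximum over m ≈ 2n−2 candidates of a
near-χ²₁ statistic, whose magnitude grows like ln m, while the flat +2
charge for the location assumes it was fixed in advance.  On homogeneous
pure-birth trees the zero-threshold rule planted spurious shifts in ~90% of
simulations.  The default therefore charges each accepted location 2·ln m
instead of 2 — i.e. a candidate must improve AICc by an extra 2(ln m − 1) —
the standard selection-aware price in changepoint model selection.  With it,
homogeneous trees stay shift-free in ~90% of simulations while planted 5×
shifts (which improve AICc by hundreds of units) are still found at or next
to the true branch essentially always.  `min_improvement=0` restores the
uncorrected rule.

## Synthetic data

* `simulate_bd_tree` / `plant_shifts`: event-driven constant-rate (or
  shift-bearing) birth-death simulation from a single stem lineage, returning
  both the complete and the reconstructed (extant-only, ultrametric) tree,
  plus the true branch→rate map and the realized shift clades.  With an
  n-tip stop the clock halts just before the next event so no tip branch has
  zero length.  Whole-tree (or single-survivor) extinction is retried up to
  a cap, then raised — never silently corrected.  Shifts are specified by
  time and (optionally) lineage index or nesting inside an earlier shift;
  forward simulation cannot address a node by its eventual tip set.
* `collapse_to_families`: slices an ultrametric species tree at a cutoff age
  (default 30 My); each crossing lineage becomes a family tip with its stem
  age preserved and richness equal to its extant descendants.  Richness is
  conserved exactly.
* `simulate_unresolved_yule_tree(_with_shift)`: exact forward sampler of the
  two-level process the unresolved-tip likelihood describes — backbone
  lineages split at λ and each newborn lineage becomes a family stem with
  probability q (default 0.5), its richness then geometric from its stem.
  This matters: drawing richness on top of an ordinary n-tip simulation
  double-counts the birth-free pendant branches and biases λ̂ upward by tens
  of percent, so recovery tests use this sampler.  The shifted variant
  regenerates one mid-depth subtree at λ·multiplier and reports the true
  shift branch.
* `simulate_taxonomic_counts`: adds Poisson synonyms to a true richness and
  thins names by an evaluation probability, labelling evaluated names by
  their true status.
* Preset tables: `seedplant_clade_table` (425-family Yule tree, λ = 0.02/My
  for a ≈300 My root, heavy-tailed log-normal family richness summing to
  2–4·10⁵ species) exercises full-scale structure;
  `seedplant_marginal_clade_table` (above) matches the published per-clade
  marginals; `null_clade_table` takes ages and nesting from a simulated tree
  but redraws every clade's richness iid — deliberately *not* summed over
  subtrees, since subtree sums grow with clade size and hence age, which
  would reintroduce the very signal the null must lack.

What the generators do not emulate: dating uncertainty (a single fixed
chronogram is assumed), taxonomic error in family circumscription, among-
lineage gradual rate variation (shifts are discrete), and diversity-dependent
slowdowns.  Passing tests therefore show the estimators and the search are
correct and well-behaved under the stated models, not that real richness
data satisfy those models.

## Problem sizes and defaults

Monte-Carlo checks run at desk scale chosen for tight, fast tests: 100
replicates for λ recovery and for shift specificity/sensitivity (~50–100
family tips, λ = 0.15/My, 60 My root, 5× shifts on 20–60-tip subclades); 100
seeds for the window-regression null (150-family trees, λ = 0.05/My);
300–1000 permutation replicates on 849-clade tables.  Pipeline defaults:
ε ∈ {0, 0.9}; 10-My windows on [20, 100) My; 1000 permutation replicates;
both model kinds in the shift search with at most 25 models.  All
randomness flows from explicit integer seeds; identical configurations give
byte-identical outputs.

## Known limitations

* The stem-age estimator ignores within-clade topology; its small-clade bias
  (E[ln S]/t ≈ λ − γ/t for pure birth) is visible in the recovery chain and
  documented there.
* The backbone likelihood treats internal branches under the reconstructed
  process even though, with unresolved tips, a surviving side lineage would
  in reality be assigned to some family — the standard approximation for
  this model class.
* AICc-guided greedy search explores one break at a time; a pair of shifts
  that only helps jointly can be missed.
* Very high fitted ε (at or near the bound) is reported with a warning and
  should be read as model misfit, not as a turnover estimate.
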