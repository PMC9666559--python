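# Methods

`stemphylo` reimplements, as a tested pipeline, the phylogenetic workflow
used to place problematic Cambrian fossils — opabiniid-like animals bearing
a frontal proboscis — on the euarthropod stem lineage: discrete-morphology
tree inference under both implied-weights parsimony and the Bayesian Mk
model, sensitivity analyses by matrix recoding, and posterior
characterisation by treespace embedding and bipartition-hypothesis
proportions.  This note records the models, the defaults and why, and the
choices made where the design was genuinely open.

## Data model

A character matrix is a taxa x characters grid of *state sets*.  Observed
cells hold one state, polymorphic cells several; missing (`?`) and
inapplicable (`-`) cells hold none and are treated identically in every
likelihood and parsimony computation — both contribute the full permitted
state set.  They are kept distinct at the I/O level only, so matrices
round-trip exactly.  Supported state symbols are `0`–`9`.  Taxon metadata
(extant/fossil flags and the named groups the hypothesis tests need:
opabiniids, radiodonts, deuteropods, Castle Bank terminal(s), outgroup)
travels in a standard NEXUS `SETS` block.

Trees are stored unrooted; rooted input has its degree-two root suppressed
on parsing.  All split-based operations (RF distance, consensus, clade
tests) use a canonical orientation: each bipartition is represented by the
side not containing the lexicographically smallest leaf.

## Implied-weights parsimony

Characters are unordered.  A character's length on a tree is the Fitch
minimum number of state changes, computed exactly for binary trees by
rooting through a reference leaf (ambiguous cells enter as bitmask state
sets).  Its minimum conceivable length is (size of the smallest state set
hitting every observed cell) − 1, a minimum-hitting-set computed exactly
(≤ 10 states).  A tree's score is the summed Goloboff fit

    F = Σ_i k / (k + e_i),       e_i = steps_i − min_steps_i,

maximised over topologies; the distortion Σ e/(k+e) = nchar − F is reported
alongside to avoid sign confusion.  The concavity constant defaults to
k = 3, the study setting.  `concavity_k = inf` selects equal-weights
parsimony (rank by total steps).

The search is multi-start random stepwise addition followed by
tree-bisection–reconnection (TBR) hill climbing with first-improvement
moves, stopping when the best score has been recovered by a required number
of independent starts (default 100, the study's retention rule) or the
start budget is exhausted (flagged).  Equal-best topologies are collected
by a bounded plateau walk and deduplicated by split set.  TNT's "New
Technology" operators (sectorial search, ratchet, drift, fusing) are out of
scope; at ≤ 60 taxa multi-start TBR with the same stopping rule is adequate
and keeps the engine self-contained.

## Mk model and Bayesian inference

The Mk model is the k-state symmetric Markov chain with uniform stationary
frequencies.  With branch lengths in expected substitutions per character,

    P(same, t) = 1/k + (k−1)/k · e^(−kt/(k−1)).

Likelihoods use Felsenstein pruning with per-node rescaling; per character,
k is the number of distinct observed states (minimum 2, states remapped to
0..k−1), the Mk-for-morphology convention.  Missing/inapplicable cells
contribute all-ones partials, polymorphic cells 0/1 indicators.  The Mkv
ascertainment correction (default on) divides each character's likelihood
by P(variable column) on the same tree, computed exactly via one extra
pruning pass (by symmetry, P(constant) = k · P(all tips in state 0)).
Gamma rate variation uses the usual discrete approximation (4 classes,
median method, renormalised to mean 1), vectorised across classes in a
single pruning pass.

Sampling is Metropolis-coupled MCMC.  Each of `n_runs` independent runs has
one cold chain and heated companions at inverse temperature
1/(1 + i·Δ), Δ = 0.1 by default, with one adjacent-pair state swap
attempted per generation.  Proposals: branch-length multiplier (weight 2),
NNI (1), SPR with uniform reattachment (1), plus multipliers on the gamma
shape and, under the hierarchical preset, on the branch-length prior mean.
The SPR Hastings factor includes the Jacobian `l_target / l_merged` of the
edge merge/split, verified by the sampling-from-the-prior test (prior mean
recovered within Monte-Carlo error).  Priors: uniform on topologies,
i.i.d. exponential (mean 0.1 by default) on branch lengths, Exp(1) on the
gamma shape.

Two strategy presets are provided as a documented reconstruction — the
study defers exact per-strategy parameter blocks to its deposited run
files, so the presets are configurable rather than hard-coded claims:
`maximise_information` (shared exponential branch-length prior, fixed
mean) and `minimise_assumptions` (the prior mean becomes a sampled
hyperparameter, i.e. extra freedom for the model to fit the data).

Run geometry is two-scale.  Desk scale (default: 2 runs x 2 chains, 200k
generations, sample every 200) finishes in minutes and is what every test
uses; paper scale (4 runs x 4 chains, ≥ 20M generations, 25% burnin)
reproduces the study geometry.  Burnin (default 25%) retains
`ceil(0.75 · n)` samples per run.  Convergence thresholds — ASDSF < 0.01
and ESS > 200 — are enforced as pass/fail only at paper scale and reported
informatively at desk scale, because desk-scale chains are deliberately
short.

ASDSF is the mean, over splits reaching frequency ≥ 0.1 in at least one
run, of the across-run sample standard deviation (ddof = 1) of split
frequencies.  ESS uses Geyer's initial-positive-sequence truncation of the
autocorrelation sum; a constant trace is reported as ESS = length, flagged.

## Treespace and hypothesis tabulation

Tree-to-tree distance is unweighted Robinson–Foulds (branch lengths are
ignored; MP trees have none).  Embedding is classical metric MDS
(principal-coordinates): eigendecomposition of the double-centred Gram
matrix, axes ordered by descending eigenvalue, each axis's sign fixed so
its largest-magnitude coordinate is positive (determinism).  RF distances
are generally non-Euclidean; negative eigenvalues are truncated to zero
with a warning.  Group overlap per axis is interval intersection over
union of the per-group coordinate ranges, plus centroids.

Each sampled tree is classified by Castle Bank placement, evaluated in
order:

1. `monophyletic_proboscis` — Castle Bank terminal(s) + opabiniids form an
   exclusive clade (some edge separates exactly that set from a side
   containing the whole outgroup);
2. `paraphyletic_grade` — Castle Bank + Radiodonta + Deuteropoda form an
   exclusive clade excluding the opabiniids;
3. `other`, with a subcategory recording the smallest clade strictly
   containing the Castle Bank terminal(s) and which named groups it touches.

On binary trees the first two are mutually exclusive (verified exhaustively
over all 10,395 8-leaf topologies in the tests).  With two Castle Bank
terminals the strict rule applies: both terminals must sit inside the
defining clade; trees splitting them across patterns fall to `other`.
Published analyses of this kind often report near-identical but distinct
category pairs built from finer subcategory boundaries; the per-tree
subcategory labels are exposed so users can build whatever aggregation they
need, and no particular boundary is guessed.

## Synthetic data

The generator emulates the study matrix's structure: 57 taxa (11 extant,
46 fossil) by 129 characters, with named clade groups (2 outgroup, 2
opabiniids, 2 Castle Bank, 6 radiodonts, 25 deuteropods, 20 unconstrained)
and fossil-biased missingness.  Defaults: state-count distribution
{2: 0.75, 3: 0.15, 4: 0.10} (a mostly binary morphological matrix);
missing-cell rates 0.45 for fossils and 0.05 for extant taxa; pure-birth
(Yule) trees rescaled to unit height; character rate 0.4 substitutions per
character over the tree height, a moderately informative regime.  Group
monophyly is enforced by growing each group as its own Yule subtree grafted
onto a backbone over group placeholders.  Characters evolve forward under
the same Mk process the inference assumes; no ascertainment filtering is
applied by default.

What the generator does *not* emulate: extinction and fossil sampling
(pure birth only), correlated character evolution, anatomy-driven
inapplicability structure, and the non-random concentration of missing data
in particular body regions.  Passing tests therefore demonstrate internal
consistency of the engines and pipeline on data obeying the model's
assumptions — not robustness to the model violations real fossil matrices
contain.

Labelled "posterior-like" tree samples with a known category mixture are
built directly: for each draw a topology of the requested category is
constructed from random subtrees (the `other` generator requires at least
two opabiniids so that no unintended focal clade can form).  Recovered
proportions concentrate around the mixture at the binomial rate.

## Problem sizes used in the tests and acceptance runs

The engines are exact, so correctness is checked at enumeration scale
(trees of 4–6 leaves against brute force; all 105 six-taxon topologies for
the search; all 8-leaf topologies for exclusivity) and behaviour at
moderate scale: the Bayesian recovery experiment uses 16 taxa x 500 binary
characters with homogeneous branch lengths of 0.15 substitutions per
character and desk-scale MCMC (2 chains, 8k generations).  Homogeneous
lengths make every split identifiable at 500 characters; raw Yule lengths
leave near-zero internal branches whose splits no method could recover, which
would test data identifiability rather than inference correctness.  The
convergence-diagnostic demonstration uses 6 taxa x 100 characters with two
runs of 25k generations.

## Numerical choices

* Score comparisons in the search use an absolute tolerance of 1e-9;
  equal-fit trees are all retained, deduplicated by split-set hash.
* Pruning rescales partials per node per character; log-likelihood agrees
  with exhaustive enumeration to < 1e-10 on 5-leaf trees.
* All randomness flows through `numpy.random.Generator` seeded per
  operation; pipeline stages derive seeds from the master seed by a CRC of
  `label:stage`, so any stage can be reproduced in isolation.
* Degenerate inputs: an all-missing character contributes 0 steps and
  log-likelihood 0; a zero distance matrix embeds to all-zero coordinates;
  a constant MCMC trace reports ESS = length with a warning.

## Known limitations

* Fitch counting is exact for binary trees only; consensus (multifurcating)
  trees are summaries, not scored objects.
* The two strategy presets approximate the published strategies'
  intent, not their exact deposited parameter blocks.
* TBR neighbourhoods are enumerated explicitly; beyond ~60 taxa the search
  slows markedly (the study's matrices are within range).
* No tip-dating, clock models, fossilised birth–death priors, Bremer or
  resampling supports, or ordered/step-matrix characters.
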