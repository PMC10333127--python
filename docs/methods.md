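# Methods

## The model

Two hierarchically dependent characters — reproduction mode (oviparous `O`,
viviparous `V`) and eggshell mineralization (membrane `m`, parchment `p`,
rigid `r`) — are amalgamated into one continuous-time Markov chain over six
states, ordered `index = 3·(O=0, V=1) + (m=0, p=1, r=2)`. The eggshell
component of the three viviparous states is *hidden*: a viviparous taxon
cannot preserve an eggshell, so its observation is the set `{V·m*, V·p*,
V·r*}` rather than a single state. This turns the classic
inapplicable-character problem into an ordinary hidden-state likelihood.

Structural constraints on the generator `Q`:

- simultaneous changes of both components in one jump are impossible
  (structural zeros), so `_ind` variants satisfy `Q = Q_repro ⊕ Q_shell`
  exactly (Kronecker sum, asserted cell-by-cell in the tests);
- `_sw` ("switch-on") variants additionally zero the three
  viviparous-background shell transitions: the eggshell can evolve only while
  the lineage is oviparous.

Rate schemes `ER` (1 parameter), `CER` (2), `CSYM` (4), `CARD` (8) crossed
with `_ind`/`_sw` give the eight SMM variants; EER is modelled separately as
a binary character (`EER_ER`, `EER_ARD`). `CER` is read as *one rate per
component character*; a one-parameter reading would duplicate `ER` and
collapse the model set to six. Reproduction-mode rates never depend on the
hidden shell background, and all three shell transitions are allowed (no
ordered-character constraint). `CARD` generators are generally not
time-reversible, which is why the marginal-ancestral-state engine defaults to
the no-reroot recursion (below).

## Observations

Codings allow ambiguity sets (`viviparous/oviparous`), unknowns (`?`) and the
inapplicable eggshell (`-`). A coding becomes a tip prior with uniform mass
over all compatible amalgamated states: a point mass for an oviparous taxon
with a known shell, 1/3 on each `V·x*` for a viviparous taxon, and — for a
mesosaur-style taxon coded "either viviparous, or oviparous with
membrane-shelled eggs" — 1/4 on each of `{O·m, V·m*, V·p*, V·r*}`. The
half/half split between the two hypotheses (rather than uniform over four
states) is equally defensible; the prior vector is exposed as data so either
convention can be supplied. Parsimony uses the same compatibility logic as
0/1 contrast rows.

## Time-scaling

Tip ages are drawn uniformly on each taxon's [LAD, FAD] interval (Myr before
present); that draw is the *only* random element of a tree sample, both
scalers being deterministic given tip ages.

- **mbl**: node ages initialise at the oldest descendant tip age; a single
  tips-to-root pass then enforces `age(parent) ≥ age(child) + vartime`
  (default 1 Myr). Tip ages never move; afterwards every edge lasts ≥
  `vartime`.
- **equal**: the root is pushed back by `vartime`; each zero-duration edge
  takes an equal share of the span from the nearest ancestral
  positive-duration edge down through the run of tied nodes (processed
  preorder, so donors are already positive). The method family is defined
  here by its contract — all durations positive, root age = naive root age +
  `vartime`, tip ages fixed — since redistribution details differ between
  published implementations; ours re-spaces each tied run evenly in one pass.

Node-calibration priors are offset gamma distributions parametrized by
(shape, minimum age, sd) with `scale = sd/√shape`, so the distribution's s.d.
equals `sd` and its mean is `offset + √shape·sd` (shape 3 throughout the
pipeline). An optional affine shift anchors an absolutely dated taxon.
Before ML fitting trees are rescaled to height 1; before MCMC to mean branch
length 0.01 — pure conditioning choices that keep rates inside optimizer
bounds and priors, undone by the likelihood's tree×c/rates÷c invariance
(tested).

## Likelihoods and ancestral states

Felsenstein pruning with per-node rescaling (log-accumulated) and per-edge
`exp(Qt)` via scipy's scaling-and-squaring, cached by edge duration;
independent characters sharing tree and `Q` are evaluated in one vectorized
pass. The root prior defaults to flat, with stationary and custom options;
the choice is recorded in every `FitResult` since reasonable software differs
here.

Marginal ancestral states: the default `no_reroot` route is an
upward–downward recursion (`P(node=j | all tips) ∝ up_j · down_j`, with the
downward message using `P_{ij}` in the parent-to-child direction), valid for
non-reversible generators. The `reroot` route literally reroots the tree at
each node and reads the root marginal; it requires reversibility and is kept
as an independent cross-check (the two agree to 1e-8 for reversible models).
Node constraints zero disallowed states' partials at a clade's ancestor;
constraining to a zero-posterior state raises an explicit zero-likelihood
signal rather than returning NaNs.

ML fitting: L-BFGS-B over log rates bounded in [1e-8, 1e3] (sized for
unit-height trees), 10 restarts by default (first at rate 1, the rest
log-uniform on [1e-3, 1e2]), 500 iterations per trial, ties between restarts
broken by restart index. Saturated data drive the estimate to the bound and
set an `at_bound` flag instead of failing. AIC = 2k − 2 logL; the "near-best"
set is ΔAIC < 2.

## Parsimony

Sankoff dynamic programming on the topology (branch lengths deliberately
ignored): an up-pass of minimal subtree costs and a down-pass of outside
costs identify, for every node, *all* states attained by some globally
minimal reconstruction, plus exact per-state counts of minimal
reconstructions (min-plus DP with multiplicities) reported as frequencies —
ties are reported, never silently broken. Forbidden steps (simultaneous
two-component moves; viviparous-background shell moves under `_sw`) cost 100,
effectively infinite: raising it to 1e6 changes no reconstruction on the
randomized battery. ACCTRAN uses Hartigan's up-pass (correct on polytomies)
and the documented convention: root takes its lowest-index preliminary state;
a child keeps the parental state when possible, otherwise the change lands on
that rootward-most eligible edge with ties again to the lowest index.

## Bayesian layer

Fixed-dimension Metropolis–Hastings on rates with multiplicative log-normal
proposals (step s.d. 0.5; the Jacobian enters the acceptance ratio). Priors:
uniform(0, 10) for single-rate models, independent exponential(mean 10) per
rate otherwise — a fixed-prior simplification of a hierarchical exponential
hyperprior, noted in every trace's metadata. Reverse-jump over rate
partitions is intentionally absent: the named model set already spans the
partitions of interest and marginal-likelihood comparison covers model
choice, keeping the sampler verifiable against closed forms.

Stepping-stone marginal likelihoods use power posteriors at Beta(0.4, 1)
quantiles, each stone warm-started from the previous one with a 20% burn-in;
the estimator is the usual sum of per-stone `log E[exp(Δβ·logL)]`. Full-scale
settings (1,000 stones × 100,000 iterations; 11M MCMC iterations, sample
every 10,000, 1M burn-in, 3 chains) are recorded in `McmcConfig.FULL_SCALE`;
desk-scale defaults (32 stones, 2,000 iterations) pass the likelihood≡1 zero
test within ±0.05 and match 1-D quadrature within 0.1. ESS uses arviz's
autocorrelation estimator (a constant trace reports ESS 1 with a warning).
Log Bayes factors are `2·(lnML_complex − lnML_simple)` with `ER_sw` /
`EER_ER` as the simple comparators.

## Synthetic data: what it emulates, what it does not

Trees come from a forward birth–death simulation that keeps extinct lineages
as fossil tips (defaults birth 0.05, death 0.02 /lineage/Myr, stopping when
the target number of lineages is simultaneously alive) — realistic extinct-tip
age structure without full fossilized-birth–death sampling, which the
pipeline does not need. FAD/LAD intervals bracket each true tip age with
uniform one-sided widths (default window 5 Myr). Trait histories are exact
Gillespie realizations recording every jump, so structural claims (one
component per jump; no viviparous-background shell change under `_sw`) are
asserted on the jump chain itself.

The amniote fixture has 80 taxa (59 extinct, 21 extant) in the
documented clade blocks, two outgroups removed before any ancestral-state
work, a ~340 Myr root with geometrically cascading node ages, characters
evolved under `CER_sw` (reproduction 0.004, shell 0.008 /Myr — a handful of
transitions across the tree, matching the sparsity such datasets show), an
independent binary EER character (rate 0.003), the viviparous-masking rule
and one mesosaur-style ambiguous tip. It matches the *shape* of the real
dataset, not its content: real codings, topology and dates are not
reproduced, so passing tests demonstrate correctness of the machinery and
recoverability under known truth, not the empirical conclusions drawn from
the real data.

## Identifiability of the root state under masking

Because every viviparous tip hides its eggshell, the eggshell component of a
viviparous ancestor is structurally unidentifiable: no amount of signal makes
the three `V·x*` states distinguishable at a node whose subtree never leaves
viviparity. The recovery harness therefore scores root recovery on the
observable components — reproduction mode always, eggshell only when the true
root is oviparous — and reports the strict six-state frequency alongside
(`root_recovery_strict`), which is bounded away from 1 by this argument, not
by estimation error.

## Numerical choices and limitations

- Edge-duration ties in pruning are cached to 15 decimals; underflow is
  handled by per-node max-rescaling accumulated in log space.
- Stationary distributions come from a least-squares null vector of `Qᵀ`;
  reversibility is detailed balance to 1e-9 (relative).
- Zero-duration edges are tolerated by the likelihood (`P(0)=I`) but the
  time-scalers never produce them.
- Acceptance thresholds in the test battery run at desk scale (e.g. 500
  characters on a 64-tip tree for rate recovery; 24–32 stones for
  stepping-stone checks), chosen as the package's own verification sizes.
- Out of scope: joint/stochastic-mapping ASR, DELTRAN, reverse-jump and
  variable-rates (per-branch σ²) models, fossilized-birth–death tip-dating
  inference, and topology estimation.
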