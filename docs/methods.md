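# Methods

## Model

A logic-regression model consists of `k` logic trees `L₁…L_k` — strictly
binary trees whose leaves are SNP literals (a 0-based column index into the
binary genotype matrix, optionally negated) and whose internal nodes carry
AND or OR — combined through a logistic link:

```
P(case | h) = g(β₀ + Σᵢ βᵢ Lᵢ(h)),   g(η) = 1/(1+e^(−η)).
```

Negation lives only on leaves; the De Morgan complement of any tree is again
a tree of this form.  A model's *size* `s` is its total leaf count, its
*score* the number of individuals whose thresholded prediction (probability
≥ 0.5 → case) equals the observed phenotype.  Coefficients are MAP
estimates under independent N(0, v) priors (default v = 10), computed by
Newton/IRLS on the penalized logistic likelihood; a singular or separated
design falls back to extra ridge damping and is flagged.  With a single
binary tree output this classification coincides with per-group majority
voting, which is what makes exhaustive-enumeration cross-checks possible.

### Solution-space embedding

Splitting a tree at every OR (distributing AND over OR) yields a forest of
AND-only conjunctions whose disjunction is evaluation-equivalent to the
tree.  A tree with score `Y` maps to the coordinate `(n, s⃗, Y)` — number of
conjunctions, their sizes, and the score; a simplified mode replaces `s⃗` by
the scalar tree size.  Because a fitted model thresholds a *sum* of tree
outputs, the Boolean function it computes need not equal any single tree:
`model_forest` therefore expands the fitted classifier over the 2^k tree
output patterns into a DNF and multiplies out the corresponding tree (or
complement) forests.  Interactions are reported from this model-level
forest: a pair/triple of SNPs counts as interacting when it co-occurs
inside one conjunction, once per reported model.  Trees with negative
fitted coefficients are first rewritten as their De Morgan complements with
positive coefficients (the intercept absorbs the shift), so reported
expressions read as positive-risk combinations.

### Model prior

The size-penalizing prior is kept in factorized form:
`p(M) = p(n_l) · p(s | n_l) · p(s⃗ | s, n_l) · Πᵢ p(q⃗ᵢ | sᵢ)` with
`p(n_l)` uniform on {1..n_max}, `p(s | n_l) = θ α^s (1−α)` normalized over
the attainable sizes `s ∈ [n_l, n_l·s_max]` (θ is exactly this normalizer;
α = 0.5 by convention), the size vector uniform over compositions of `s`
into `n_l` parts of at most `s_max`, and `p(q⃗ᵢ | sᵢ)` uniform over the
`C(N, sᵢ)` leaf-indicator vectors.  The tests verify by enumeration that
the prior sums to one over a small model space.  The prior is exposed for
reporting and analysis; the search itself ranks models by score, with the
acceptance rule below governing downhill moves.

## Search

`F` fish agents (default 12) each hold one model.  Each agent draws a
bootstrap sample of the rows once at initialization; **search acceptance is
decided on the agent's bootstrap sample** (this is what keeps the school
diverse — twelve replicates of the data landscape), while **f_best
announcement, local bests and the global-best record use full-data scores**
so agents are comparable.  Initial trees have size ~ U(1, s_max) with
uniform SNPs.

Per iteration:

1. The best agent is announced (highest full-data score, ties to the lowest
   agent id) and HOLDs.
2. Every other agent samples a behavior from the mixture
   (RANDOM, FOLLOW, KPDIST) = (0.2, 0.5, 0.3) — the mixture is a design
   choice, exposed in `RunConfig`:
   * **RANDOM**: one of ADD SNP / DEL SNP / ALT SNP / ALT OPT with
     probability 1/4 each, uniform choices; infeasible moves are resampled.
   * **FOLLOW** (toward f_best): with `f(s)` the normal density centred on
     `s_best` with variance `σ² = max(0.25, mean((sᵢ − s_best)²))`, clamped
     to [0,1] and used directly as a probability — if `sᵢ > s_best`, DEL
     with probability `f(sᵢ)` (victim leaf drawn ∝ 1 − P(j)), else ALT; if
     `sᵢ < s_best`, ADD with probability `1 − f(sᵢ)` (new SNP ∝ P(j)), else
     ALT; if equal, ALT always.  "ALT" means ALT SNP or ALT OPT with equal
     probability when both are feasible.  Replacement SNPs are drawn ∝ P(j′)
     over SNPs outside the model (a `strict_literal_alt` flag inverts this
     to 1 − P, the alternative textual reading).
   * **KPDIST** (away from f_best): mirror image — `sᵢ > s_best`: ADD with
     `1 − f(sᵢ)`, else ALT; `sᵢ < s_best`: ALT with `f(sᵢ)`, else DEL;
     equal sizes: ADD or DEL with probability 1/2.  Its SNP draws run away
     from importance (add unimportant ∝ 1 − P, drop important ∝ P).
3. A proposal that improves the agent's bootstrap score is accepted; a
   worse one is accepted with probability
   `Q = min{1, v^{k/2}|V̂*|^{1/2} / (v^{k*/2}|V̂|^{1/2}) · e^{a−a*}}`
   where, treating the response conjugately on the tree-output design Ω,
   `V̂ = (Ω′Ω + I/v)⁻¹`, `β̂ = V̂Ω′y` and `a = y′y − β̂′V̂⁻¹β̂` is the
   residual error term.  Identical proposals give Q = 1 and a smaller `a*`
   raises Q.  (A `literal_rejection` flag implements the alternative
   reading "rejected with probability Q"; a `q_against_best` flag compares
   against the global best instead of the agent's own model.)
4. Every `I_max = 10` iterations the importance table is refreshed —
   `V(j) = (1/F) Σ_k (N_k − N_k^{−j})` with `N_k` the correctly classified
   out-of-bag rows of agent k's model refitted on its bootstrap rows and
   `N_k^{−j}` the same after deleting every occurrence of SNP j (an emptied
   model falls back to the bootstrap-majority rule; agents with empty OOB
   contribute zero) — and every agent's model is pruned by stepwise
   elimination (below).  Selection probabilities are
   `P(j) ∝ max(V(j), ε) + ε` with ε = 0.5 so every SNP stays reachable.
5. The run stops when the global-best score has not improved for `B`
   iterations (default 50) or at a hard cap of 10,000 iterations.  The
   global-best record is monotone: it is replaced only by a strictly higher
   score, or by an equal score with strictly fewer leaves (parsimony
   tie-break).  A final importance refresh keeps the reported table
   consistent with the reported models.

Agents own independent random streams spawned from the master seed, so a
run is bit-reproducible and agent updates could be evaluated concurrently
between the synchronization points (announcement and refresh); the shipped
implementation executes them sequentially.

### Stepwise elimination

For each SNP leaf, a partial F statistic compares the linear regression of
the phenotype on the model's tree-output columns with and without that
leaf: `F = (RSS_reduced − RSS_full) / (RSS_full / (M − p))`.  Leaves are
removed greedily one at a time (smallest F first, recomputed after each
removal) while `F ≤ F_out` (default 4.0 ≈ the 95th percentile of the null
χ²₁, so a pure-noise leaf survives ~5% of sweeps); the last leaf is never
removed.  Removing leaves one at a time matters for duplicated SNPs: the
first copy has F = 0 exactly and is dropped, after which the second copy's
F becomes informative.

## Synthetic data

The generator reproduces the benchmark protocol: a pool of `n_pool`
haplotypes (default 40,000) over `n_sites` segregating sites (default
1,000); each site's derived-allele count is drawn from the neutral
site-frequency spectrum `P(count = i) ∝ 1/i` and placed on uniformly random
haplotypes, so every column is segregating by construction.  Sites are
independent — the default backend models allele-frequency structure, not
linkage disequilibrium, which is irrelevant for the causal/noncausal
discrimination metrics; an optional `msprime` coalescent backend provides
LD-structured haplotypes.  A set of causal sites is drawn and a random
binary AND/OR expression planted over them (negation off by default, since
the causal model is mutation-driven), rejection-resampled until 5–95% of
pool haplotypes evaluate to 1; if no expression over a causal-site draw
satisfies the guard, new sites and ultimately a new pool are drawn.  The
phenotype equals the expression output with probability `risk` (agreement
probability; risk = 1 is deterministic), `n_cases`/`n_controls` rows are
sampled uniformly without replacement within class and shuffled, and
finally every allele of the sampled matrix is flipped independently with
probability `noise` (noise is applied after sampling, matching the
protocol's ordering).

What this emulates: the neutral frequency spectrum, exact case-control
sampling, probabilistic genotype-phenotype coupling and genotyping error.
What it does not: linkage disequilibrium (default backend), population
structure, covariates, missing data.  Recovery rates measured here
therefore speak to the optimizer and the importance statistic, not to
confounding robustness on real cohorts.

A consequence of planting *random* expressions over SFS-distributed sites
is worth noting: OR-heavy expressions are usually dominated by one
high-frequency site that alone explains nearly every individual, so the
remaining causal sites carry almost no conditional signal and no method can
recover them from 2,000 samples.  Identified-causal counts under this
generator are correspondingly conservative.

## Numerical and design choices

* IRLS: ≤ 50 Newton steps, step-norm tolerance 1e-9, sigmoid clipped at
  |η| = 35; ties at probability exactly 0.5 classify as case.
* Acceptance ratio computed in log space; non-positive-definite posterior
  covariance or non-finite error terms reject the proposal with a
  diagnostic.
* σ² of the size density floored at 0.25 and the density clamped to 1, so
  a degenerate swarm (all sizes equal) still mixes behaviors.
* Tree moves address uniformly chosen eligible positions; ALT SNP must
  change the literal (identical redraws are rejected); DEL of a repeated
  SNP removes one occurrence.
* Model bounds: per-tree size ≤ s_max = 8, trees per model ≤ k_max = 3
  (standard logic-regression scale).
* Dataset layout: TSV with a header of SNP ids and the phenotype as last
  column; diploid VCF/PLINK dosages are recoded dominant (any mutant → 1)
  or recessive-pair (two binary columns per site: homozygous-mutant and
  carrier).  Indices are 0-based internally, 1-based (`X1`…) in output.
* Tree depth is not bounded separately from size.

## Evaluation metrics

Because the benchmark literature normalizes interaction-detection errors
inconsistently, three labeled variants are always computed from a selected
SNP set S against the causal set C: the literal ratios
`|C∖S|/|S|` and `|S∖C|/|S|`; the conventional miss rate `|C∖S|/|C|` and
false-discovery `|S∖C|/|S|`; and a per-site type I `|C∖S|/N`.  The
benchmark tables this package reproduces are matched by ranking SNPs by
importance, selecting the top `|C|`, and reporting the per-site type I with
the top-k type II — the normalization under which the published
type I/type II/identified columns are mutually consistent.  Selection from
a fitted swarm supports three modes: the stepwise-pruned global best
(default), the union over all agents' final models, and the top-k ranked
selection used for benchmark tables.

## Desk-scale settings

Experiments and the acceptance script run each repeat with B = 300 stable
iterations and a 1,500-iteration cap (seconds per repeat at M = 2,000,
N = 1,000) and average 10 repeats per configuration; these are the
package's desk-scale study sizes, chosen so a full benchmark grid completes
on one CPU while the swarm reliably reaches score convergence.

## Known limitations

* The identified-causal counts of the full-scale published benchmark are
  only directionally comparable: the original optimizer's F, B and behavior
  mixture are unpublished, and the generator's expression shapes (see
  above) cap how many causal sites are statistically recoverable.
* Only binary phenotypes are supported; quantitative responses are out of
  scope.
* The swarm is single-host; the parallel contract is deterministic
  sequential execution.
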