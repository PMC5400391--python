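# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `famturn`. It states how quantities are computed;
empirical numbers appear only where the test suite or the acceptance
script computes them.

## Coordinate conventions

A species tree is rooted, binary, and ultrametric within a relative
tolerance (default 1e-6; configurable). A *branch* is identified by the id
of the child node it subtends; the root subtends no branch. Internal nodes
without labels receive deterministic ids (`N` + postorder index), so branch
ids are stable across reads of the same file. Events that a reconciliation
places above the root are booked on the pseudo-branch `ROOT`, which has no
length and is excluded from every regression table; this is the
conservative choice for events that cannot be assigned an exposure.
Non-binary trees are rejected rather than silently resolved, because the
duplication/loss counting semantics below assume binary nodes.

## Birth–death simulation (bdsim)

A family starts as a single gene lineage at the species root and
immediately enters both root-child branches (no stem edge; this makes the
root-survival filter symmetric and well defined). Along a branch each
lineage independently duplicates at rate λ and dies at rate μ; sampling is
exact — per lineage, an Exp(λ+μ) waiting time followed by a Bernoulli
choice between duplication and loss (competing risks), recursing on both
daughter lineages. At a speciation node every surviving lineage is copied
into both child branches. The observable gene tree prunes all-extinct
subtrees and suppresses unary nodes; the true event log (branch, type,
time) is kept alongside.

Filters reproduce standard guest-tree-simulator practice: observable leaf
count within [4, 10 000] by default, per-species copy number within
[0, 10 000] (species-level absence allowed), and the *root-survival
filter*: at least one extant gene in each of the two subtrees below the
species root, i.e. the family is still basally present across the clade.
"Lost on one side of the root" is interpreted as the whole root-child
subtree, not merely the root edge. Batch sampling rejects until the
requested number of families passes, aborts with a diagnostic when the
acceptance rate falls below 1e-4, and treats a family whose event count
exceeds a cap (500 000) as a rejected attempt — a guard against the heavy
upper tail of the critical (λ=μ) process, astronomically rare at the
default rates.

## Reconciliation (reconcile)

Leaves map to their species; internal node v maps to
`M(v) = LCA(M(left), M(right))`; v is a duplication iff `M(v)` equals a
child's map. A duplication is booked on the branch above `M(v)`. Losses use
the standard depth-difference convention: on gene edge (u, v), every
species node strictly between `M(u)` and `M(v)` contributes one loss on its
off-path child branch; when u is a duplication the path starts at `M(u)`
itself. Absence of the family outside the subtree it maps into is *not*
counted as loss — families are analyzed on the subtree where they are
basally present, and basal presence itself is a separate filter
(`filter_families`: gene-tree root maps to the species root, and at least
one event on a real branch; the second clause uses real-branch events
because those are the regression's data). Single-leaf gene trees reconcile
with zero events.

`split_at_root_duplications` repeatedly replaces a tree whose root is a
duplication by its two root subtrees; split parts become families
`name.1`, `name.2`, … This mirrors the practice of splitting families that
duplicated before the base of the clade, giving each basal copy its own
exposure and random intercept.

LCA reconciliation is the minimum-event reconciliation; the test suite
verifies this against exhaustive enumeration over all valid maps for every
gene-tree shape and species assignment up to 4 leaves on a 3-taxon tree
and a seeded sample of 5–6-leaf trees on a 4-taxon tree. Parsimony counts
lower-bound the truth: events on lineages that left no surviving
descendants are invisible. The hidden fraction grows with the expected
number of events per family; with ≲1 expected event per family inferred
totals equal the truth for >95% of simulated families (a property test).

## Regression (turnover)

The response per (family, branch) row is the duplication count, the loss
count, or their sum (turnover). The linear predictor combines branch
predicates (sets of branch ids), family covariates (numeric flags used as
is, categoricals dummy-expanded dropping the first level), and their
products; `log t_b` enters as an offset, so coefficients are log event
rates per unit branch length. Branch lengths must be positive; rows can be
dropped by branch id (used to exclude basal lineages from per-clade
models). The design matrix is checked for full rank.

The naive model is an ordinary Poisson GLM (statsmodels IRLS). An all-zero
response raises instead of returning a −∞ intercept.

The mixed model adds a per-family intercept u_f ~ N(0, σ²) and maximizes
the *marginal* likelihood over (β, log σ). Within a family the random
effect enters every row identically, so the family likelihood depends on
the data only through S_f = Σ y and C_f = Σ exp(x'β + log t); the
1-D integrals

    l_f(u) = σ u S_f − C_f e^{σu} − u²/2 + const

are strictly concave, their modes are found by damped Newton iterations
vectorized across families, and the integrals are evaluated by adaptive
Gauss–Hermite quadrature centered and scaled at the mode (default 7 nodes;
1 node is exactly the Laplace approximation; 15 nodes reproduce brute-force
numerical integration to better than 1e-6 on test data). The outer
optimization is BFGS started from the naive fit and log σ = log 0.5, with
a Nelder–Mead fallback. Wald SEs come from the central-difference observed
information of the marginal log-likelihood, inverted with an eigenvalue
floor (numerical differentiation near flat optima can produce spurious
non-positive curvature). σ̂ → 0 is a valid boundary fit: it is flagged,
the fit is polished against the exact σ=0 (GLM) likelihood, and fixed-
effect SEs are taken at σ fixed. An independent cross-check against
lme4::glmer (same quadrature order) agrees on coefficients and σ to ~1e-3;
Wald SEs agree on average but can differ by tens of percent on a given
dataset because both implementations differentiate numerically.

Linear contrasts are Wald z tests of c'β = 0 with Holm (default),
Bonferroni, or no adjustment across the supplied set. A zero contrast
returns estimate 0 and p = 1. Single-step max-z adjustment in the style of
multcomp is deliberately not claimed: reproducing a particular simultaneous
adjustment is out of scope, and Holm is uniformly valid.

Per-family tests fit `turnover ~ 1 + focal-lineage` per family (no random
effect — one family has nothing to share) and report BH q-values across
families. Families whose events fall entirely on or off the focal lineage
are flagged as boundary fits (the coefficient diverges; its Wald p is
conservative); zero-event families are skipped and reported.

`enrichment_fisher` is the conditional two-sided exact test
(scipy.stats.fisher_exact) plus the sample odds ratio ad/bc; the test
suite checks it against direct hypergeometric enumeration.

## Calibration experiments (calibrate)

The rate grid is 12 log-spaced points, 0.00057–0.341 events per lineage
per MY, with λ = μ, so true turnover is twice the grid rate. At each rate
a fixed number of families is simulated subject only to the leaf-count
bounds (desk profile 200, full profile 1000); the root-survival filter is
applied afterwards, so the surviving pool's composition — many families at
low rates, a handful at the top — is an outcome of the experiment and is
recorded.

*Rate recovery* reconciles each rate's survivors and fits intercept-only
Poisson models for turnover, duplication and loss; `exp(β̂₀)` is the
estimated event rate per unit branch length. Rates with fewer than 10
survivors are skipped. Two survivor-conditioning biases are inherent to
this estimator and worth stating plainly: (i) the root filter censors loss
events on the two root-child branches (a basal loss usually eliminates the
family), biasing the loss — and through it the turnover — estimate low;
(ii) surviving basal duplications multiply the number of gene lineages on
every interior branch while the exposure stays t_b, biasing the
duplication estimate high, increasingly so at higher rates. The two
partially cancel in the turnover estimate. `drop_basal=True` removes the
two basal branches from the regression and largely eliminates (i). The
loss estimate remains biased low at the top of the grid under any variant,
because family-extinguishing losses are exactly the ones the filter
removes.

*Type-I experiment*: the root-surviving families from the whole grid are
pooled and collapsed to one row per family (by Poisson additivity the
family totals are sufficient for family-constant covariates — an identity
the test suite checks). For each permutation dataset, 100 families drawn
without replacement are labeled "immune" and `turnover ~ immune` is fitted
naively and with the random intercept; the Wald p of the immune
coefficient is recorded and the rejection fractions at α = 0.05 are
reported. Because the labels are random, the truth is the null; the naive
model's rejection fraction measures how badly among-family rate variation
corrupts its standard errors, while the mixed model should reject at
roughly α. Per-dataset seeds derive from (seed, constant, dataset index),
so the experiment is bit-reproducible. Fit failures are excluded and
counted (none occur at desk scale in the shipped configuration).

## Phylostratigraphy (phylostrat)

A hit qualifies if the alignment covers ≥40% of the query protein and has
≥20% identity; a gene's raw age is the maximum divergence age among
proteomes with a qualifying hit (one qualifying deep hit is enough — the
deliberate, conservative max rule), and genes with no qualifying non-self
hit receive the youngest stratum's age rather than being dropped, keeping
the regressions' n interpretable. Hits to the focal proteome are excluded.

Normalization: raw age is regressed on log-transformed, mean-centered
expression (pseudocount 1 for zero counts) or protein length, one
predictor at a time; the normalized age subtracts the fitted effect.
Centering makes the correction mean-preserving; normalized ages may leave
the raw age range. Age–induction analyses are a logistic regression of the
induced flag on age (Wald inference; perfect separation raises) and
per-category 2×2 χ² tests of each of the four categories (young =
Schizophora, intermediate = Insecta, old = Protostomia, ancient =
Opisthokonta) against the rest, without continuity correction by default.
Raw ages are binned to the youngest category at least as old as the gene;
continuous normalized ages go to the nearest category boundary, clamped to
the category range. A joint expression+length correction is intentionally
not offered — the single-predictor corrections are the documented,
comparable procedures.

## Synthetic data (fixtures)

The 14-taxon fixture tree (7 Drosophilids, *Glossina*, *Musca*, 5
mosquitoes; Muscidae sister to Glossinidae+Drosophilidae within
Schizophora, Culicidae outgroup) has a 250-MY root depth and
timetree-style internal calibrations (Schizophora crown 70 MY, Drosophila
crown 50 MY, Culicidae crown 180 MY). The topology and depths are
realistic for the clade; the exact branch lengths are stand-ins, and all
rate checks therefore compare estimates with the simulator's own truth,
never with published per-branch rates. Annotation tables default to a 3.3%
immune fraction with uniform class assignment. The phylostratigraphy
generator plants: a detection-bias dependence between expression and
apparent age (latent threshold model, slope 0.8 SD per SD), a logistic
age–induction effect (default −5.5e-4 per MY around an 8.1% baseline), and
hits that make deepest-hit reconstruction exact at the default thresholds,
plus non-qualifying deeper decoys. What passing these tests shows is that
the estimators recover planted effects of realistic size; they cannot show
that real BLAST bit-score structure, incomplete proteomes, or annotation
error are handled — those never enter the generator.

## Scale choices

Simulation-backed checks run at a reduced "desk" profile — 200 families
per rate and 300 permutation datasets — chosen so the full suite completes
in minutes on a single core while keeping the Monte-Carlo error of a
rejection fraction near one percentage point; the full-scale profile
(1000/1000) is one config switch away. Seeds are explicit everywhere; two
runs with the same manifest are identical.

## Known limitations

- Parsimony undercounts events; the regression inherits the survivor-
  conditioning biases described above. Estimated rates are best read as
  *observable-event* rates per unit branch length.
- The mixed model fits a single Normal random intercept per family; branch-
  specific random effects, zero inflation, and count-profile likelihoods in
  the style of CAFE are out of scope.
- Gene trees are consumed as given; topological error correction is the
  caller's problem.
- Wald inference throughout; likelihood-ratio intervals are not provided.
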