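# Methods

## Model and search

The regressor searches the space of expression trees over binary operators
`+ − × ÷`, unary functionals `sqrt square cube exp ln`, descriptor
variables, and real constants. Depth is counted with a bare terminal at
depth 0; the default depth cap is 4, which bounds expressions at 31 nodes
and keeps them legible. The search is a generational genetic program:

1. **Initialization** — random trees of depth 1–2 ("grow": a target depth
   is drawn uniformly, one root-to-leaf spine reaches it, siblings grow to
   random smaller depths). Terminals are constants with probability 0.2,
   drawn uniformly from [−10, 10]; the pKi scale spans roughly 5–11, so
   ±10 covers intercepts, and least-squares refitting makes the initial
   values nearly irrelevant.
2. **Selection** — tournaments of size 5 with replacement; ties on
   combined fitness break toward the smaller tree, then randomly.
3. **Variation** — a selected pair is recombined by one-point subtree
   exchange with probability 0.7, then each child is subtree-mutated with
   probability 0.2 (replacement subtree depth 0–2). Offspring violating
   the depth cap or a structural filter are re-drawn from the same parents
   up to 50 attempts, then the parents pass through. Structurally
   identical parents exchange the subtree at the same position, so cloning
   pressure cannot masquerade as variation.
4. **Scoring** — constants are fitted by least squares, the domain filter
   (D or D2, when active) is applied to the *fitted* tree — certifying the
   expression that is actually scored — and the stability-weighted fitness
   is computed. One elite (the all-time best filter-passing individual) is
   carried into each generation, which guarantees the best-so-far fitness
   is non-increasing.

Two implementation choices depart from the plainest reading of the loop
and exist because the scaled-down populations used in testing (50
individuals) otherwise collapse to copies of one individual within ~10
generations: (a) crossover and mutation are applied sequentially (the
semantics of DEAP's `varAnd`, the idiom of the library family this method
descends from) rather than as mutually exclusive draws; (b) when filling a
generation, offspring whose constant-blind structure already occurs in the
new population are re-drawn up to 50 attempts before a duplicate is
admitted. Two trees with the same shape and variable placement are
duplicates for search purposes regardless of their constant values,
because constant fitting maps both to the same function; any variable-free
subtree likewise folds to a single constant marker. Neither choice alters
the model class, the filters, or the fitness.

## Constant optimization

Constants are optimized by damped least squares
(`scipy.optimize.least_squares`, trust-region reflective, numerical
Jacobian) from the tree's current constants, single start. Rows where the
candidate evaluates invalidly contribute a large finite penalty residual
(10^6), steering the optimizer away from invalid regions while keeping the
objective finite; all residuals are clipped at that magnitude so wildly
divergent intermediate constants cannot overflow the objective. The fit
never worsens: on optimizer failure or regression the starting constants
are kept. Public default: tolerance 10⁻⁸, 200 iterations; inside the GP
loop the cap is 50 iterations, which the small trees searched here never
approach at convergence.

## Filters

* **V** and **F** are purely structural (constant-value invariant): V
  rejects any repeated variable anywhere in the tree (the strict reading;
  a per-additive-term reading exists but is not implemented); F rejects
  nesting of two operators from the same group — {sqrt}, {square, cube},
  {ln, exp} — along any root-to-leaf path.
* **D** evaluates the candidate on probe points and rejects it if any
  evaluation is invalid or leaves the target range. When no external
  probe set is supplied the engine draws 10,000 uniform points in a box
  1.5× the training span per feature, centered on the data.
* **D2** estimates the candidate's range over the domain box by 5 bounded
  L-BFGS-B minimizations of f and of −f (numerical gradients, 200
  iterations, ftol 10⁻⁹), started from training rows clipped into the box
  (uniform draws when no data are supplied). The candidate passes iff the
  estimated [min, max] lies inside the target range. Any optimizer query
  point that evaluates invalidly marks the expression undefined inside the
  box and rejects it — an expression undefined in-domain cannot be
  certified. Multi-start local search is not certified global
  optimization; interval arithmetic is out of scope, mirroring the
  method's own design.

`DomainSpec` defaults to the training split (per-feature min/max box,
observed response range). Deriving it from training+test is available but
flagged as information leakage; a user-supplied spec is the right choice
when the feasible response range is known a priori — e.g. synthetic
studies, or assay-specific potency bounds.

## Stability metrics

Perturbation magnitudes are δx_j = 0.1·std(x_j) (training std, ddof=1;
zero for degenerate features) and δc_j = 0.1·|c_j|. The magnitudes define
no sign or sampling scheme; the implementation perturbs all coordinates
simultaneously and deterministically, reporting the mean of the +δ and −δ
root-mean-square displacements. Deterministic fitness keeps a GP run fully
reproducible from its seed; symmetric averaging removes sign bias. A
seeded stochastic variant (random sign vectors) is available via
`StabilityConfig(scheme="stochastic")` for sensitivity checks. If a
perturbed evaluation is invalid at some row, that row's displacement is
set to `invalid_displacement` — the engine sets it to the target-range
width (default 4.0 pKi, a typical potency span), so instability to leaving
the sample is punished at the scale of the whole response range.
Constant-free trees have STBL_c = 0 by definition. Weights default to
(1.0, 1.0) for the single-penalty fitness variants and (0.5, 0.5) for
FITNESS_XC; a sweep grid λ ∈ {0.01 … 1.0} is supported through the config.

## Synthetic data

`generate_synthetic` draws descriptors uniformly from a per-feature box
and adds i.i.d. Gaussian noise to a known ground-truth expression. This
emulates the shape-recovery problem — can the search re-discover a known
functional form at a known noise level — and the preset truths (linear,
rational, saturating exponential) cover every operator group. It does
*not* emulate real descriptor tables: real descriptors are correlated,
discretely distributed (counts), and heteroscedastic, and real potency
noise is not Gaussian. Passing recovery tests therefore demonstrates
search and filter correctness, not expected field performance.

Recovery experiments use a user-supplied `DomainSpec`: the generator's box
and the truth's range over it widened by ±3σ. With a target range taken
from observed y values, any well-fitting surface of a multi-feature
monotone target — including the generating formula — is rejected by D2,
because the box corners carry no samples and the function's true extremes
exceed every observed value. That is an artifact of low-noise synthetic
data; with real assay data the response range is noise-dominated and the
observed range is the natural choice.

## Problem sizes

Tests and the acceptance script run the search at population 50 × 30
generations with 5 independent seeds per experiment, on synthetic sets of
80–120 compounds — the regime where one run takes seconds to tens of
seconds on a single core. The full-scale defaults (200 × 200) are the
standard operating point for real studies and are exercised only through
their configuration values.

## Benchmarking protocol

Every cell of the experiment matrix (feature set × train ratio × split)
uses one split shared byte-identically by all methods. Relative RMSE is
computed per execution against the mean predictor before aggregation;
methods are compared by medians with 40th/60th-percentile bands. SVR
features are standardized inside the pipeline (train statistics only) and
C, ε, γ are chosen by seeded 5-fold CV over logarithmic grids
(C ∈ 0.1…1000, ε ∈ 0.01…1, γ ∈ 10⁻³…10 — conventional spans for
standardized descriptors); MLR and the symbolic regressor see raw
descriptor scales, so printed coefficients are in descriptor units. A GP
cell that cannot initialize under its filters scores as the mean predictor
and is flagged.

## Descriptors

The ten substituent descriptors map to rdkit: aromatic/total ring counts,
HBA/HBD counts, heavy-atom count, Crippen logP, rotatable bonds, TPSA,
molecular weight. Van der Waals volume uses the conformer-free
Bondi-sphere sum with the standard bond/ring overlap correction
(V = Σ 4/3·π·r³ − 5.92·N_bonds − 14.7·R_arom − 3.8·R_aliph). logP/TPSA
parameterizations drift across toolkit releases, so tests assert
structure-forced counts and toolkit self-consistency rather than pinned
literature values.

## Known limitations

* The D2 certificate is only as strong as multi-start local optimization;
  a pathological expression with a very narrow spike can evade it.
* Formula recovery at population 50 × 30 generations is stochastic;
  experiments report success counts over 5 seeds rather than a guarantee.
* No symbolic simplification: algebraically equivalent forms (e.g. a
  product written two ways) are distinct individuals, and reported
  formulas may contain redundant constant arithmetic.
* No multi-objective selection, island models, or parallel populations.
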