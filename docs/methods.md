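# Methods

## Model

A trial is declared as k prognostic factors plus one behavioural
outcome (k+1 surveyed concepts) and one intervention concept. The fuzzy
cognitive map is a signed, weighted digraph over these m = k+2 concepts.

**Fuzzy aggregation.** Relationship answers are linguistic: a strength
term from an ordered vocabulary plus a direction, or an Unsure sentinel.
The default scale has five terms with symmetric triangular membership
functions on the strength axis [0, 1], peaks at 0.1/0.3/0.5/0.7/0.9 and
half-width 0.2, shrunk symmetrically where a support would cross an axis
boundary (so the edge terms have half-width 0.1). Keeping every triangle
symmetric inside [0, 1] makes each term's centroid coincide with its
peak, which keeps defuzzified weights interpretable (a unanimous
"strong, increase" panel yields exactly +0.7); clipping asymmetrically
instead would bias the extreme terms toward the centre. Overlapping
supports are intentional — the reality described by "strong" partly
includes that of "very strong". Scales with any number of terms and any
non-negative membership functions are supported; centroids are computed
by numerical integration on a 2001-point grid.

Per relationship, Unsure and missing answers are dropped from numerator
and denominator; each remaining (term, direction) pair receives a
confidence factor equal to its endorsement share, and the edge weight is
the confidence-weighted sum of direction-signed centroids. Opposite
directions therefore cancel partially rather than being resolved by
majority vote, preserving minority views in proportion to their support.
A relationship answered only with Unsure gets weight 0 (absent edge).
Aggregation is invariant to participant order and to replication of the
whole answer set.

**Simulation.** The update is the standard synchronous rule
V_j(t+1) = f(Σ_i W_ij V_i(t)) with f(x) = tanh(λx), λ = 1 by default.
A `self_memory` flag optionally adds V_j(t) inside the sum — both
conventions exist in the FCM literature; the plain rule is the default.
The intervention concept is clamped every iteration (1 = on, 0 = off);
it is an external driver, not a dynamic concept. The outcome concept
starts at 0 because it is unknown at baseline; only the *difference*
between runs is interpreted. Convergence means a maximum absolute
concept change below ε = 1e-5; each run caps at 100 iterations and a
non-converged run (the map may orbit a limit cycle under synchronous
updates) is summarized as the mean state over the final c = 10
iterations. tanh keeps every iterated value in (-1, 1), so

    E_i = V_outcome(on) - V_outcome(off)  ∈  (-2, 2).

The expected change is implemented as a difference, not a ratio: the
off-intervention outcome frequently stabilizes at 0 under tanh, where a
ratio would be undefined. Note one deliberate asymmetry in terminology:
sigmoidal transfer functions are sometimes described as keeping concepts
in [0, 1]; tanh, used here, is the bipolar variant with range (-1, 1),
and all downstream statistics are defined on that scale.

**Allocation.** Participants sorted ascending by E_i (ties broken by
participant id under a stable sort, for auditability) are dealt
cyclically over the n groups, so sizes differ by at most 1 and the E
distributions per group are near-identical. Baseline comparators:

- simple randomization — iid uniform group per participant;
- random permuted blocks — each full block is a uniform draw over the
  multiset orderings (enumerable via `enumerate_block_sequences`; a
  trailing partial block is a uniform prefix);
- stratification — quantile bins (default 4) of one factor, permuted
  blocks within each bin; a constant factor collapses to one stratum.
  Quantile binning is used because it guarantees non-empty strata for
  continuous factors.

**Randomization of the sorted sequence.** Because the protocol is
deterministic, a shuffle proportion p reintroduces randomness:
`uniform` performs round(p·N/2) disjoint swaps of uniformly chosen
position pairs (≈ a fraction p of individuals move); `distance` draws
the swap partner with probability ∝ 1/(1+d) in sequence distance d,
favouring nearby (similar-E) swaps, which hurt balance least; `binned`
permutes only within contiguous bins of the sorted sequence, fully
preventing distant swaps. p = 0 is always the identity.

**Sequential design.** For s recruitment waves of size b = ceil(n/s),
the map is rebuilt from the cumulative answers of waves 1..t before
allocating wave t; wave-t participants are sorted by their E under that
map and the group cycle continues from the global count already
allocated (rather than restarting at group 0), keeping overall sizes
balanced. Earlier assignments are never revisited; s = 1 reproduces the
fixed-sample protocol exactly.

**Missing data.** Relationship answers missing or Unsure are already
tolerated by the aggregation. Missing factor values must be imputed
before simulation: `mean` (observed factor mean), `normal` (draw from a
normal fitted to observed values, clipped to [0, 1]) or `constant`
(0.5, the scale midpoint). Observed values are never altered.

## Quality metrics

A `QualityReport` gives per-group size/mean/min/max of E and, across
groups, the population SD (divisor = number of groups — the groups are
the entire population of interest, not a sample) of the means, minima
and maxima, plus the absolute extremes over all participants (both the
per-group and absolute extremes are of interest; both are reported).
`overlap` scores agreement between two allocations as the fraction of
unordered participant pairs co-grouped in both or separated in both
(Rand-index style), which avoids any group-label matching problem.

## Synthetic study conditions

The generator exists so that every pipeline stage is testable without
participant data. It emulates the structure of behaviour-change
cohorts, not any specific survey's numbers:

- **Factors** (all truncated to [0, 1] by rejection sampling):
  sedentary-skewed exercise ~ inverse-Gaussian(mean 0.25, shape 0.5);
  food intake = exercise + 0.15 + noise (an environment that promotes
  eating over exercising); weight discrimination = 0.9 × obesity +
  noise (discrimination proportional to body size); age, depression,
  stress, obesity ~ truncated normals with means 0.45/0.30/0.50/0.55.
  Dependent factors are sampled after their parents; cyclic dependence
  is rejected.
- **Relationship answers**: each of the 56 items has its own
  categorical distribution over (term, direction) pairs plus Unsure —
  a modal term (biased toward moderate-to-strong consensus) with
  discretized-Laplace spread, one dominant direction, a 10% dissenting
  (opposite-direction) share and 5% Unsure. Every participant answers
  every item independently from its distribution.
- **One bundled panel.** A real trial has a single shared reality
  behind the answers, so the per-item profiles are fixed once (the
  bundled panel) and seeds vary only the cohort: factor values and
  individual answer draws. The bundled panel was selected from
  candidate random profiles by two model-validation screens applied
  before any method comparison: (a) the aggregated map must
  *discriminate* participants — expected changes spread continuously
  over the cohort rather than collapsing to one shared value (a map
  under which everyone responds identically makes allocation trivially
  moot and matches no behavioural cohort); (b) among such panels, E
  should be as stable as possible under sampling noise of the
  aggregation. Under the bundled panel the map orbits a limit cycle, so
  E is the tail-window mean and varies smoothly with the initial factor
  values; roughly 420 distinct E values appear in a 430-person cohort.
- **Missingness injection**: relationship answers degrade to Unsure in
  independent per-round passes (expected final fraction
  1-(1-rate)^rounds; a direct target-fraction mode is also provided,
  since stacking rounds compounds quickly — 12 rounds at 5% already
  implies ≈46%); factor missingness blanks an exact uniformly chosen
  count of cells, round(proportion × cells).

What passing tests on these conditions do **not** show: the generator's
parameter values are plausible defaults, not survey-calibrated facts,
and per-item independent answering omits within-respondent responder
styles (optimists rating everything stronger). Conclusions about the
*relative* behaviour of allocation methods transfer; absolute SD values
do not.

## Experiment design choices

The seeded studies in `fcmalloc.experiments` use sizes chosen to give
stable Monte-Carlo estimates at desk scale: 100 virtual trials of
n = 430 for the superiority study, 200 seeds for the shuffle sweep,
20-30 seeds per batch size for the sequential curve, and n = 5000 with
20 seeds per missingness level for the imputation sweep. The shuffle
sweep couples p levels by common random numbers — one full disjoint
pairing is drawn per seed and each p applies its prefix — which leaves
each p's marginal distribution unchanged (a uniform prefix of a uniform
disjoint pairing is itself one) while sharply reducing the variance of
cross-p comparisons. The sequential curve is fitted with a power law
a·b^-c by OLS in log-log space.

In the missingness study, all methods allocate from the imputed records
but are scored against the complete-data expected changes — the
quantity imputation is trying to recover; the map itself is unaffected
(only factor answers are blanked).

## Numerical notes and degenerate inputs

- Convergence freezes each run at its first sub-tolerance step, so a
  converged state satisfies the fixed-point equation to ε.
- Weight matrices validate |W_ij| ≤ 1 and a zero diagonal; defuzzified
  weights are bounded by the largest term centroid (≤ 1).
- Quantile stratification of a constant factor yields one stratum; an
  all-Unsure relationship yields weight 0; an empty tally defuzzifies
  to 0 by definition.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; sub-streams are derived by `SeedSequence` spawning so methods
  never share draws.

## Known limitations

- With only the intervention clamped, a fully converged map sends every
  initial state to one of finitely many fixed points, so E is piecewise
  constant (participants cluster on a few values); continuous E spreads
  arise only from oscillatory maps via tail averaging. Conversely,
  tail-mean E is more sensitive than a fixed point would be to small
  perturbations of the weights or factor values — visible as the rapid
  quality plateau in the sequential study and the steep degradation
  under imputation. Clamping observed participant characteristics would
  give smooth, robust E but is a different modelling contract.
- The cyclic deal after sorting carries a systematic half-gap bias
  (group j+1 receives the larger member of each consecutive sorted
  pair). It vanishes ~1/n but is material in tiny trials: for n ≤ 8 and
  two groups the cyclic split can be beaten by over a third of all
  equal-size partitions. An optimal-partition search would be easy at
  such sizes; the cyclic rule is kept for fidelity and determinism.
- Minimization (Pocock–Simon) and the maximal procedure are out of
  scope, as are cluster-level allocation and KDE-based imputation
  (plain mean/normal/constant are implemented).
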