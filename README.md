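# fcmalloc

Covariate-adaptive allocation of participants in randomized controlled
trials (RCTs) for behaviour change, driven by a fuzzy cognitive map (FCM)
built from the participants' own baseline questionnaires.

## The problem

Standard allocation methods — simple randomization, random permuted
blocks, stratification — balance trial groups on group size or on
prognostic factors considered in isolation. But behavioural outcomes
emerge from *interactions* among prognostic factors (stress drives food
intake, discrimination drives stress, exercise lowers both, ...), so
groups balanced factor-by-factor can still differ widely in how their
members would respond to the intervention. `fcmalloc` balances the
predicted response itself:

1. **Design.** The practitioner lists k prognostic factors and one
   behavioural outcome. All k(k+1) directed relationships among these
   k+1 concepts are surveyed unless explicitly pruned; an intervention
   node with fixed signed edges (+1/-1) to its target factors is added
   automatically. A baseline questionnaire is generated from the design.
2. **Fuzzy aggregation.** Each participant rates each relationship with
   a linguistic strength term ("weak" ... "very strong"), a direction
   (increase/decrease), or "Unsure". Per relationship, the fraction of
   non-Unsure respondents endorsing (term, direction) is that pair's
   *confidence factor*; the edge weight is the confidence-weighted sum
   of direction-signed term centroids,

       W_ij = Σ_(t,d) c_(t,d) · d · centroid(μ_t),   W_ij ∈ [-1, 1],

   where μ_t is the term's triangular fuzzy membership function.
3. **Simulation.** With the participant's own factor values V_i(0) as
   initial concept values, the map is iterated with the standard
   synchronous update V_j(t+1) = tanh(λ Σ_i W_ij V_i(t)) until the
   outcome stabilizes (tolerance ε = 1e-5) or an iteration cap is hit
   (non-converged runs are reported as the mean over the final c
   iterations). The *expected behavioural change* is
   E_i = outcome(intervention clamped to 1) − outcome(clamped to 0).
4. **Allocation.** Participants are sorted by E_i and dealt cyclically
   over the n groups (the i-th goes to group i mod n), so groups end up
   with nearly identical distributions of expected change. Sequential
   (batch) recruitment, partial re-randomization of the sorted sequence,
   and mean/normal/constant imputation of missing factors are supported,
   alongside simple randomization, permuted blocks and stratification
   for comparison.

Allocation quality is the population standard deviation, across groups,
of the groups' mean (and min, max) expected change — the smaller, the
more similar the groups at baseline.

## Worked example

The package ships self-contained study conditions: a seven-factor
obesity-prevention trial (intervene on exercise, measure excess weight)
with a fixed answer panel and a sedentary-skewed synthetic population.

```python
from fcmalloc import AllocationConfig
from fcmalloc.evaluation import compare_methods
from fcmalloc.synthetic import generate_sedentary_cohort

design, records, answers = generate_sedentary_cohort(n=430, seed=0)
results = compare_methods(records, answers, design,
                          AllocationConfig(n_groups=4, seed=1))
for method, (alloc, report) in sorted(results.items(),
                                      key=lambda kv: kv[1][1].sd_mean):
    print(f"{method:35s} sizes={alloc.sizes()}  SD(mean E)={report.sd_mean:.4f}")
```

prints

```
fcm                                 sizes=[108, 108, 107, 107]  SD(mean E)=0.0028
stratified:depression               sizes=[105, 107, 110, 108]  SD(mean E)=0.0201
stratified:stress                   sizes=[107, 106, 109, 108]  SD(mean E)=0.0290
stratified:food intake              sizes=[111, 106, 105, 108]  SD(mean E)=0.0295
stratified:obesity                  sizes=[107, 111, 105, 107]  SD(mean E)=0.0297
stratified:weight discrimination    sizes=[107, 107, 108, 108]  SD(mean E)=0.0359
blocks                              sizes=[108, 107, 108, 107]  SD(mean E)=0.0425
simple                              sizes=[105, 106, 110, 109]  SD(mean E)=0.0449
stratified:exercise                 sizes=[106, 110, 108, 106]  SD(mean E)=0.0468
stratified:age                      sizes=[107, 109, 108, 106]  SD(mean E)=0.0474
```

The FCM-sorted allocation produces groups whose mean expected change
agrees to ±0.003 while every conventional method leaves an order of
magnitude more imbalance — and which single stratification factor works
best cannot be known in advance (here depression, with exercise and age
among the worst).

The same pipeline is scriptable from the shell:

```bash
fcmalloc simulate --n 430 --seed 0 --out responses.csv --design-out design.json
fcmalloc evaluate --design design.json --responses responses.csv \
                  --groups 4 --seed 1 --outdir run/
```

which writes per-method allocation CSVs, a JSON quality report with
pairwise allocation overlaps, and a reproducibility manifest.

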