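# hfselect

Hybrid feature selection for predicting the per-cycle success of
IVF/ICSI infertility treatment (and, more generally, any binary
clinical outcome on a tabular cohort).

Clinical cohorts for assisted reproduction carry dozens of candidate
predictors — hormone doses, ages, oocyte and embryo counts, embryo
quality grades, prior treatment history — of which only a handful
drive the outcome. Single feature-selection families each have blind
spots: filters ignore the model, embedded methods are tied to one
model class, wrappers are accurate but expensive on the full feature
set. `hfselect` chains them:

1. **Split** the cohort 80/20 (stratified by outcome).
2. **Pre-select** with four filter/embedded methods: variance
   threshold (VT), ANOVA-F k-best, L1-penalized linear selection, and
   random-forest importance selection.
3. **Score the four methods with a hesitant fuzzy set (HFS).** Each
   method *x* gets the element
   `h(x) = {ACC, AUC, F-score, (MCC+1)/2, PPV, recall}` of its six
   evaluation criteria on [0, 1]. Its *deviation degree*

   σ̄′(h) = (1/l) √( Σ over ordered pairs (γᵢ − γⱼ)² ),  l = |h|

   measures how much the criteria disagree, and the *score function*
   SF(h) = 1/σ̄′(h) ranks methods: the method whose criteria agree most
   closely wins.
4. **Wrapper search** (SFS, SBS, floating SFFS/SFBS, random search)
   over the winner's reduced feature pool, scoring candidate subsets by
   stratified k-fold cross-validated accuracy of a random forest, down
   to a target of k = 7 features.
5. **Report** held-out-test profiles (ACC, AUC, MCC, F, PPV, recall)
   for every arm plus the per-step CV trace (avg_score, std_dev,
   std_err, 95% ci_bound).

MCC — the Matthews correlation coefficient
`(TP·TN − FN·FP)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))` — is carried
throughout because the outcome is imbalanced (~32% success).

Because the original two-center patient dataset is not publicly
deposited, the package ships a synthetic cohort generator
(`hfselect.simulate`) that emulates its shape: 1000 cycles, 38
predictors, 31.7% prevalence, and 7 informative predictors (`FSH`,
`FAge`, `oocytes`, `16Cells`, `compact`, `GIII`, `unsuccessful`) with
planted adverse effects. Ground truth is returned alongside, so
selector quality is measurable.

## Worked example

```bash
hfselect simulate --n 1000 --p 38 --prevalence 0.317 --seed 1 --out cohort.csv
hfselect run --data cohort.csv --outcome outcome --seed 1 --out results/
```

or in Python, scoring four published-style evaluation profiles:

```python
>>> from hfselect import HesitantFuzzyElement, score_function, rank_methods
>>> profiles = {
...     "VT":    (0.681, 0.55, 0.62, 0.57, 0.65, 0.68),
...     "kBest": (0.786, 0.77, 0.77, 0.743, 0.79, 0.79),
...     "L1":    (0.781, 0.74, 0.76, 0.737, 0.79, 0.78),
...     "Tree":  (0.79, 0.75, 0.77, 0.75, 0.79, 0.8),
... }
>>> scores = rank_methods([score_function(HesitantFuzzyElement(m, v))
...                        for m, v in profiles.items()])
>>> for s in scores:
...     print(f"{s.method_id:6s} deviation={s.deviation:.5f} SF={s.score:.3f}")
kBest  deviation=0.02342 SF=42.707
Tree   deviation=0.02799 SF=35.729
L1     deviation=0.02909 SF=34.372
VT     deviation=0.07179 SF=13.930
```

k-best wins (smallest spread among its six criteria, hence the largest
score), so the pipeline hands its ~19-feature pool to the wrapper
stage; the tree-based method is the runner-up kept for comparison
arms. `hfselect compare` runs wrapper-alone vs winner-pool vs
runner-up-pool on the same split to isolate the effect of
pre-selection.

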