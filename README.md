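# heatrr

Discriminating atrial fibrillation (AFib) from atrial flutter with irregular
ventricular response (AFlu) using only short RR-interval series is hard for
clinicians and for data-driven classifiers alike — both rhythms can produce
fast, irregular ventricular responses that look the same on a surface ECG,
yet they call for different treatments. `heatrr` implements an
*expert-model-enhanced* approach for this task: instead of learning directly
from the raw intervals, it fits a mechanistic model of multilevel
atrioventricular (AV) block to each sample by exact inverse simulation and
classifies on the physiologically interpretable quantities that fit produces.

It is aimed at researchers in cardiac electrophysiology and biomedical
time-series modelling who want a reproducible, testable implementation of
the method with a synthetic benchmark standing in for private clinical data.

## The model and the fit

A regular atrial rhythm with cycle length Δa is filtered through a cascade of
up to three blocking levels. Each level conducts *n* of every *n*+1 incoming
signals (ratios may alternate, e.g. 2:1 / 3:2) and is either **Type II**
(Mobitz — fixed conduction delay, abrupt drop) or **Type I** (Wenckebach —
the *k*-th conducted beat of a cycle is delayed by *c* + (*k*−1)·δ, resetting
after the dropped beat). The conducted times of the last level yield the
simulated RR intervals.

The inverse problem finds, over five registered blocktype presets and a 1 ms
parameter grid (Δa ∈ [175, 400] ms, further narrowed per blocktype by the
observed mean RR),

```
F(x*) = min over x = (Δa, blocktype, offsets, increments) of
        ‖ simulated_RR(x) − observed_RR ‖₂
```

with any candidate deviating by more than 150 ms on a single interval
discarded as infeasible. The search is an exact, deterministic enumeration
(vectorised per block structure, with sound pruning that never changes the
result, verified against a scalar brute-force oracle). A small optimum means
"a regular atrial rhythm explains this sample" (AFlu); a large or infeasible
optimum means it does not (AFib). The optimal objective `F(x*)` is the
decisive classification feature; the fitted Δa*, blocktype and conduction
constants are interpretable by clinicians. Moving-horizon fits, N-gram
subsequence statistics, SVM and CNN classifiers, and a repeated stratified
10-fold cross-validation harness complete the pipeline. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Fit the block model to a jittered 4:3 Wenckebach sample (true Δa = 240 ms,
δ = 20 ms, plus 5 ms measurement noise):

```python
import numpy as np
from heatrr import MAVBModel, MAVBParams, BlockLevel, forward_simulate

truth = MAVBParams(240, 1, (BlockLevel("I", ((4, 3),), 50, 20),))
rng = np.random.default_rng(0)
observed = np.round(forward_simulate(truth, 22).ventricular_rr
                    + rng.normal(0, 5, 22))
res = MAVBModel(observed).fit()
print(res.summary())
```

```
Multilevel AV block inverse fit
===============================================
n intervals                  22
candidates evaluated   13671175
feasible                   True
objective F(x*) [ms]     21.190
atrial cycle length       240.0 ms
blocktype id                  1
  level 1: Type I   ratio 4:3          offset 0  delta 20 ms
residual RMSE             4.518 ms
```

The solver searched ~13.7 million grid candidates and recovered the
generating parameters exactly — atrial cycle length 240 ms, a 4:3 Wenckebach
level with a 20 ms delay increment — with a residual norm of 21.2 ms, i.e.
about 4.5 ms per interval, exactly the injected measurement noise. On an
AFib-like (irregular) sample the same fit returns a large or infeasible
objective; that contrast is what the classifier uses.

The same pipeline is scriptable from the shell:

```sh
heat simulate --n-per-class 190 --seed 1 --out bench/
heat fit bench/samples.csv --out solutions.json
heat features bench/samples.csv --feature-set heatSolution --out features.csv
heat cv features.csv --model svm --folds 10 --repeats 10 --seed 1
heat scan bench/samples.csv --index 8 --lo -400 --hi 400 --out scan.csv
```

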