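# parcs

Multiple change-point detection in the mean of univariate and multivariate
time series, with a block-permutation bootstrap significance test that
tolerates temporally dependent (moving-average) noise.

Abrupt shifts in the mean — attractor transitions in neural population
activity, sudden jumps in behavioural performance during learning, regime
changes in environmental records — violate the stationarity assumed by most
downstream statistics. This package is for analysts who need to locate such
shifts, decide which are real, and recover the underlying step model
(baselines and jump sizes), including for spike-count data and for many
covariates that share common change points.

## The method in brief

A step in the mean of `x` becomes a *bend* in its CUSUM curve
`y_t = Σ_{τ≤t}(x_τ − ⟨x⟩)`. The curve is fitted by paired adaptive
regressors — hinge-spline pairs `h⁺_{t,c} = (t−c)·1_{t−c}`,
`h⁻_{t,c} = (c−t)·1_{c−t}` at integer knots:

    ŷ_t = β̂₀ + Σ_m [ β̂⁺_m h⁺_{t,ĉ_m} + β̂⁻_m h⁻_{t,ĉ_m} ]

with knots placed by greedy forward selection to a liberal bound `L`, pruned
back to order `M`, and ranked by explained variance. The slope change
`β̂⁺_m + β̂⁻_m` at a knot estimates the step size `w_m`, and the bending
statistic `S = |β̂⁺_m + β̂⁻_m|` is tested, knot by knot in rank order,
against an empirical null built by permuting contiguous blocks of the
residual (no-change) series — block length `q + 1`, where the moving-average
order `q` is read off the residual autocorrelation function. A classical
CUSUM test (`S = max_t |y_t|`) and the binary-segmentation baseline built on
it are included for comparison.

## Worked example

```python
from parcs import StepModelSpec, simulate, Parcs

spec = StepModelSpec(T=100, cps=(20, 60), weights=((1.0,), (2.0,)),
                     sigma=1.0, seed=7)
x = simulate(spec)                       # one noisy realization, T x 1

res = Parcs(x, order=3).fit()            # PARCS_3: up to three candidate CPs
det = res.test_significance(alpha=0.05, n_boot=1000, block_size=1, seed=0)
print(det.summary())
```

```
Change-point detection (block-permutation bootstrap)
============================================================
Block size k:     1
Significant CPs:  [60, 23]
------------------------------------------------------------
rank   loc          S     thresh        p  decision
   1    60     1.8824     0.4539   0.0010  significant
   2    34     0.3436     0.7471   0.3526  rejected
   3    23     0.8470     0.5262   0.0010  significant
------------------------------------------------------------
step at t=60: w-hat = [+2.124]
step at t=23: w-hat = [+1.383]
```

The model offered three candidate knots; the bootstrap accepted the two
near the true change points (60 exactly; 23 three steps from the true 20 —
the small first step is the hard one at this noise level) and rejected the
spurious knot at 34, whose bend (0.34) sits well inside its null
distribution (p ≈ 0.35). The inverted step estimates `ŵ ≈ +2.1` and `+1.4`
recover the simulated jumps of 2 and 1. For dependent noise, omit
`block_size` and the pipeline estimates the MA order and sets `k = q̂ + 1`
itself; `detect_changepoints(x, M=3, seed=...)` wraps the whole chain in one
call.

A command-line interface mirrors the library:

```
parcs simulate --config spec.yaml --output x.csv --seed 1
parcs fit      --input x.csv --order 3
parcs order    --input x.csv --order-fit 3
parcs detect   --input x.csv --max-cps 3 --block-size auto --seed 1
parcs binseg   --input x.csv --max-depth 1
parcs experiment --config exp.yaml --output results/cell
```

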