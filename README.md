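# bpsweep

White-box exploration of the Bertalanffy–Pütter parameter space for
tumor-growth time series.

## The problem

Given a sparse tumor-volume trajectory v(t) — a dozen or so caliper or imaging
measurements over weeks — which growth law generated it? The Bertalanffy–Pütter
family

```
dv/dt = p·vᵃ − q·vᵇ ,   a < b ≤ 3
```

contains the classical models as special cases (Verhulst/logistic at a=1, b=2;
Gompertz in the limit b→1⁺) and, for p, q > 0, saturates at the equilibrium
volume v_eq = (p/q)^(1/(b−a)). Fitting all four parameters by simulated
annealing or gradient descent is slow (CPU-days per tumor) and opaque.
`bpsweep` implements a fast, fully explainable alternative:

1. **Gradient targets.** Estimate y′(t) = dv/dt at every timepoint by finite
   differences (second-order central interior, one-sided endpoints) — no
   simulation in the fitting loop.
2. **Exact fits by Cramer's rule.** For a fixed exponent pair (a, b) the model
   is linear in (p, q): two sampled timepoints determine them exactly as
   ratios of 2×2 determinants, `p = |S₁|/|Z|`, `−q = |S₂|/|Z|`, where
   `Z[j,k]` holds term j (vᵃ or vᵇ) at sampled timepoint k and `Sⱼ` is Z with
   row j replaced by the targets. Every coefficient is a closed-form,
   differentiable function of the data — a white box with zero
   hyperparameters.
3. **Exhaustive sweep.** Repeat 20 times per exponent pair with random
   timepoint draws, score each candidate by the SSE of predicted vs estimated
   gradients over *all* timepoints, keep the best, and do this for every pair
   on the 0.01-step grid (44,850 pairs for a < b ≤ 3) — seconds, not days.
   The resulting **accuracy surface** SSE(a, b) shows the valley of
   plausible growth laws at a glance.
4. **Validation on synthetic tumors.** Generate trajectories from known
   parameters in the data-like region, re-run the sweep, and measure the
   **narrowing fraction** F: the fraction of the exponent grid scoring
   strictly better than the generating pair. Small F means the method
   localized the truth; the percentile of F across tumors quantifies how much
   of parameter space a practitioner can discard with a given confidence.

A companion `theory` module reproduces the gradient-flow convergence results
that motivate avoiding descent-trained models: even the simplest regularized
linear network admits an "information-free" fixed point at Σz²/(2β) under the
m=1, n=2 loss, and a toy ReLU network cannot fit small targets exactly for
any β > 0.

## Worked example

Simulate a 14-point synthetic tumor from a known law (a=1.60, b=2.45,
p=5·10⁻⁴, q=5.6·10⁻⁷, v₀=300), then sweep the exponent grid:

```python
>>> import numpy as np
>>> from bpsweep import BertalanffyPutter, BPParams, GridSpec, simulate_bp
>>> from bpsweep.recovery import default_schedule

>>> true = BPParams(p=5e-4, q=5.6e-7, a=1.60, b=2.45)
>>> traj = simulate_bp(true, 300.0, default_schedule())   # 14 points, 114 days
>>> np.round(traj.volumes, 1)
array([ 300. ,  337.7,  382.5,  436.3,  501.3,  580.1,  676.1,  792.9,
        934.5, 1104. , 1302.3, 1526.4, 1767. , 2009.4])

>>> model = BertalanffyPutter(traj)                       # finite-difference targets
>>> res = model.fit(grid=GridSpec(step=0.05, b_max=3.0, a_min=1.0),
...                 trials=20, seed=7)
>>> print(res.summary())
        Bertalanffy-Putter exponent-grid sweep
========================================================
No. timepoints:        14    Grid pairs:             820
Trials per pair:       20    Seed:                     7
Grid step:           0.05    Failed pairs:             0
--------------------------------------------------------
Best exponents:  a = 1.75       b = 2.05
Coefficients:    p = 0.0003697  q = 3.312e-05
SSE (gradient targets):  0.240403
Equilibrium volume (p/q)^(1/(b-a)):  3110.19
========================================================

>>> res.narrowing_fraction((1.60, 2.45))
0.06097560975609756
```

From 14 noisy-gradient points the sweep does not pin the exact exponents (the
surface minimum sits at (1.75, 2.05)), but the generating pair ranks inside
the best 6.1% of the 820-pair grid: 94% of parameter space can be discarded
before any expensive refinement. `res.plot_surface()` renders the SSE
heat map; `res.predict()` forward-simulates the best-fit law.

The same pipelines are available from the shell:

```bash
bpsweep make-fixture --output tumor.csv
bpsweep sweep --input tumor.csv --step 0.01 --trials 20 --seed 7 \
              --output surface.csv --plot surface.png
bpsweep recover --n-traj 200 --seed 1 --out recovery.csv
```

Every command writes a `<output>.run.json` sidecar with the fully resolved
configuration, so runs are exactly reproducible.

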