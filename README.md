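# marshrisk

Tidal marshes survive rising seas only while they can accrete vertically
as fast as the water rises. The Holocene stratigraphic record preserves
the outcomes of thousands of such races: *transgressive* contacts, where
tidal-flat sediment overlies marsh deposits, mark marsh retreat
(a **positive sea-level tendency**), and *regressive* contacts mark marsh
expansion (**negative tendency**). Because glacial isostatic adjustment
(GIA) drove rates of relative sea-level rise (RSLR) from strongly
negative to well above modern rates across a formerly glaciated region,
a database of dated contacts spans exactly the rate range expected under
twenty-first-century climate forcing.

`marshrisk` is a pipeline for turning such a database into a
probabilistic retreat forecast, for coastal scientists and sea-level
modellers:

1. **`database_io`** — read, validate and filter index-point databases
   (erosional contacts are excluded: they only bound the transition age),
   encode tendencies as a binary response, and tabulate tendency
   proportions in 0.5 mm/yr rate bins.
2. **`gia_rates`** — assign each point the RSLR rate at its median
   calibrated age by centred 200-yr (±100 yr) differencing of a
   piecewise-linear GIA RSL curve (native resolution 1000 yr).
3. **`monotone_pspline`** — fit a Bayesian monotone penalized B-spline
   Bernoulli model of retreat probability versus rate.
4. **`projection_coupling`** — push Monte Carlo sea-level projection
   ensembles through the fitted curve to date future vulnerability.
5. **`synthetic_data`** — generate GIA-style curves, databases with
   tendencies drawn from a known truth curve, and calibrated projection
   ensembles, so everything is testable without the (request-only)
   observational database.

## The model

With `y_i = 1` for a positive tendency and `x_i` the RSLR rate (mm/yr),

```
y_i ~ Bernoulli(p_i),          logit(p) = Σ_k b_k(x) α_k,
α_k − α_{k−1} ~ N(0, σ_α²),    α_k − α_{k−1} ≥ 0,
```

where `b_k` are K cubic B-spline basis functions of the rate. The
first-difference penalty smooths the curve; the non-negativity
constraint on the differences makes every posterior probability curve
monotone non-decreasing in the rate. Posterior draws come from an
adaptive Metropolis-within-Gibbs sampler (JIT-compiled; 4 chains,
convergence checked by split R-hat). Future retreat probability at a
site is the posterior-mean curve evaluated at the *cumulative maximum*
of each projection sample's trailing 20-year rate, averaged over the
Monte Carlo ensemble.

## Worked example

The numbered scripts under `analysis/` run the whole chain on synthetic
data (seed 1):

```sh
python analysis/01_simulate.py          # database + curves + ensembles
python analysis/02_assign_rates.py      # gradual filter + rate assignment
python analysis/03_fit_tendency_model.py
python analysis/04_project_retreat.py
```

which prints, among other things:

```
retained 779 gradual-contact points (318 erosional excluded)
rate range: -4.2 to 10.1 mm/yr
max R-hat: 1.011 (converged: True)
p = 0.9 reached at 8.9 mm/yr
P(retreat | +7.0 mm/yr) = 0.79 (95% UI 0.64-0.92)
P(retreat | -0.2 mm/yr) = 0.15 (95% UI 0.11-0.20)
tilbury_like / RCP8.5: P > 0.8 first in 2070.0 (P = 0.94 by 2300)
tilbury_like / RCP2.6: P > 0.8 first in 2120.0 (P = 0.90 by 2300)
```

Read: of 1097 synthetic contacts, 779 gradual ones enter the fit; the
fitted probability of retreat reaches 0.9 near 9 mm/yr (this run's
synthetic truth puts it at 7.4 — the upper tail of the rate
distribution is data-poor, so the estimate there is conservative); and a
subsiding site first exceeds an 80% expected retreat probability around
2070 under the high-emission scenario versus around 2120 under the
low-emission one. A retreat probability of 0.90 corresponds to 9:1 odds
of retreat versus expansion or stability.

The same pipeline runs on real data via the `marshrisk` CLI
(`simulate`, `rates`, `fit`, `project`, `report`) given index-point,
curve and ensemble files in the documented CSV formats.

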