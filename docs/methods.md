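# Methods

## Observational unit and coding

A sea-level index point is a dated stratigraphic contact. Its
*tendency* records the direction of change in marine influence:
positive (transgressive contact, marsh retreat), negative (regressive
contact, marsh expansion), or none (marsh keeping pace). The response
is coded `positive → 1` and both `negative` and `none → 0`: the
quantity modelled is the probability that a marsh, observed at a given
RSLR rate, was retreating. `encode_tendencies(..., none_as_zero=False)`
exposes the stricter two-class coding that drops no-tendency points
instead. Erosional contacts are excluded before modelling because their
age only bounds the transition (unknown hiatus); the filter logs every
exclusion with a reason code and is idempotent.

Only the median calibrated age is used; calibrated ranges are carried
as metadata. Ages must lie in 0–12,000 cal yr BP.

## Rate assignment

GIA model output arrives as RSL node series with ~1000-yr resolution.
The rate at an index point is the centred finite difference of the
piecewise-linearly interpolated curve over a 200-yr window:

    rate = [RSL(age − 100) − RSL(age + 100)] / 200 yr × 1000  (mm/yr)

positive = RSL rising toward the present. No smoothing is applied
beyond the piecewise-linear interpolant, and no extrapolation: points
whose window leaves the curve support raise an error (or are flagged
with `on_out_of_range="flag"`) rather than being one-sided differenced.
On a window inside a single segment the rate equals the segment slope
to machine precision; across a kink it is the length-weighted average
of the two slopes. Rate and age uncertainties are *not* propagated into
the regression covariate — a known limitation shared with the standard
practice this pipeline follows.

## The monotone P-spline Bernoulli model

y_i ~ Bernoulli(p_i), logit(p) = Σ_k b_k(x) α_k with K cubic B-splines
on equally spaced knots spanning the observed rate range. Smoothness
comes from a first-order difference penalty, α_k − α_{k−1} ~
N(0, σ_α²); monotonicity from constraining those differences to be
non-negative, so every retained draw's probability curve is
non-decreasing in the rate.

Parameterization: (α₁, δ₂..δ_K, log σ_α) with δ_k = α_k − α_{k−1}.
Priors:

| parameter | prior | default | rationale |
|---|---|---|---|
| α₁ | Normal(0, 10²) | — | weakly informative on the logit scale |
| δ_k (monotone) | half-Normal(σ_α), i.e. the difference penalty truncated at 0 | — | direct reading of penalty + constraint |
| δ_k (unconstrained) | Normal(0, σ_α²) | — | plain first-difference penalty |
| σ_α | half-Cauchy(scale 1) | 1.0 | heavy-tailed smoothing scale; lets the data choose roughness |
| K | — | 12 | penalized splines are insensitive to K beyond sufficiency; configurable |

### Sampler

Adaptive random-walk Metropolis-within-Gibbs, chain kernel compiled
with numba. Because the basis is a partition of unity, the linear
predictor is η = α₁ + Σ_j δ_j C_j(x) with C_j = Σ_{k≥j} b_k, so each
component update costs O(n). Two move families per iteration:

1. component moves on α₁, each δ_j, and log σ_α (proposals violating
   δ ≥ 0 are certain rejections — valid Metropolis under a truncated
   prior);
2. compensated pair moves (α_j += e, δ_{j+1} −= e) that change a single
   coefficient α_j. These are essential: α₁ and the boundary δ's are
   nearly unidentified individually (a level/difference ridge) and mix
   an order of magnitude faster with the pair moves (ESS for α₁ rose
   from ~30 to ~900 at default settings).

Step sizes adapt in batches of 50 during burn-in toward a 0.44
acceptance rate, then freeze (preserving detailed balance after
burn-in). Defaults: 4 chains × 20,000 iterations, 10,000 burn-in,
thin 5. Convergence is reported (split R-hat on every parameter via
arviz; `converged` flag at R-hat ≤ 1.05), never silently fixed.
Identical seed + config gives identical draws; chain seeds derive from
the config seed.

### Summaries

The probability curve reports the posterior mean of p on a grid with
2.5/97.5 percentile bands. The *posterior mean of p* is used (not p at
posterior-mean coefficients); `ModelPosterior.p_draws` exposes draws
for the alternative. Outside the fitted support the curve is held flat
at the boundary value — required because projected future rates can
exceed the largest Holocene rate in the data; this is deliberately
conservative (no upward extrapolation of the trend).
`rate_at_probability` inverts the mean curve by first grid exceedance
refined with linear interpolation, returning a `NotReached` sentinel
(with direction) when the target is unattained.

## Projection coupling

Per Monte Carlo sample: trailing 20-year average rates on the decadal
grid (rate(t) = [RSL(t) − RSL(t−20)]/20, cm → mm; trailing rather than
centred so no future data enter), then the running maximum of that rate
series, then the mean-curve probability at the running maximum; the
timeline is the arithmetic mean over samples. The cumulative maximum
composed with a monotone curve makes timelines non-decreasing, so the
first decadal year with probability strictly above the threshold
(default 0.8; no sub-decadal interpolation) is well defined. The
running maximum starts at the first year with a full 20-yr lookback;
earlier years carry no value. Probability composition uses the
posterior-mean curve only; pushing full posterior draws through the
ensemble is possible via `p_draws` but is not the default.

## Synthetic data

The generator emulates the study conditions, not any particular
dataset:

* **Curves** — per-millennium rate sequences integrated to RSL nodes
  (0–12,000 cal BP, 1000-yr resolution), three regimes: near-field
  (early deglacial fall, mid-Holocene highstand of ~2 m above present
  at ~4000 cal BP, late fall; rates within −7.7 to 6.0 mm/yr), margin
  (attenuated highstand), far-field (decelerating monotone rise; early
  rates up to 15.2 mm/yr, late 0–4.6 mm/yr). 5% multiplicative jitter;
  internal segment slopes round-trip exactly through `compute_rate`.
* **Index points** — n = 1097 by default with 1.7% no-tendency and
  28.8% erosional shares (the printed composition of the observational
  database); ages 65% from N(5500, 1300²) yr BP and 35% uniform,
  reproducing the mid-Holocene concentration and hence the deliberate
  age–rate confounding (rates 0–3 mm/yr over-represented). Tendencies
  are Bernoulli draws from a known truth curve, default
  logistic(−1.5 + 0.5x): p ≈ 0.9 near 7 mm/yr and ≈ 0.1 near −2 mm/yr,
  echoing the shape of the Holocene fit without claiming its values.
  With this truth and covariate mix the synthetic database is
  negative-heavy (~30% positive) — an emergent property of the
  confounding, retained deliberately.
* **Ensembles** — stylized two-term trajectories (linear land motion +
  stochastic quadratic climate term) on a decadal 2000–2300 grid,
  affinely recalibrated so the realized 5th–95th percentile of 2100
  rise matches the scenario target (default 23–123 cm, the
  high-emission range at a subsiding Thames-estuary-like site; 7–83 cm
  for the low-emission scenario). Equal quantile targets give a
  deterministic ensemble. Not emulated: spatial fingerprints, ocean
  dynamics, per-component budgets, regional geometry.

Passing the recovery and calibration tests therefore shows the
estimator is consistent and well calibrated *under Bernoulli sampling
from a smooth monotone truth with realistic covariate imbalance*; it
cannot show robustness to rate measurement error, spatial correlation
between index points, or non-monotone truth — none of which the
generator produces.

## Validation experiments and problem sizes

* Parameter recovery: n = 800 clean two-class points, default sampler;
  RMSE of the mean curve vs truth over the central 90% of rates
  (boundary regions are data-poor and excluded by design), and the
  p = 0.9 rate threshold vs the analytic inverse (±0.5 mm/yr).
* Linear-limit oracle: K = 2, degree 1, monotonicity off reduces the
  model exactly to linear-logit regression; posterior means are checked
  against the maximum-likelihood fit at n = 5000 (within 3 posterior
  SDs).
* Calibration: 50 replicates of n = 400 at reduced sampler settings
  (2 chains × 4000, half burn-in, thin 4) — sizes chosen to keep the
  full replicate study to a few minutes while leaving Monte Carlo error
  on coverage near 1%.
* Coupling identities are exact (constant-rate ensembles, prefix-max,
  duplication invariance) and are tested as such.

## Numerical choices and degenerate inputs

* Rate bins are half-open [a, a + 0.5) anchored at multiples of the
  width (edge convention stated, not inherited).
* Basis evaluation clamps to the support (flat extrapolation); direct
  evaluation outside the support with `clip=False` is an error.
* Threshold crossing uses strict `>` on the decadal grid.
* Single-class datasets fit (the CLI refuses without `--force`) but are
  flagged `boundary_degenerate`; small or one-class data warn that the
  posterior is prior-dominated.
* Prior-predictive draws (`prior_only=True`) are used to verify the
  priors do not accidentally concentrate p away from (0, 1).
* "Very likely" ensemble summaries mean the 5th–95th percentile range
  (probability 0.90).

## Known limitations

No measurement-error-in-x model; no spatial or regional random effects;
no radiocarbon calibration (median ages are inputs); flat extrapolation
understates risk growth beyond the Holocene rate range by construction;
the ensemble generator matches quantile targets only, not the
underlying physics.
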