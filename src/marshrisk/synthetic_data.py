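"""Synthetic stand-ins for the observational database and projections.

The real Great British Holocene sea-level database is available only on
request, and the probabilistic projection framework behind the future
RSL ensembles is external; this module generates structurally faithful
substitutes so the whole pipeline is testable end to end:

* GIA-style RSL curves at 1000-yr resolution for three loading regimes —
  ``near_field`` (formerly under thick ice: early deglacial RSL fall, a
  mid-Holocene highstand above present, late fall), ``margin``
  (attenuated highstand), and ``far_field`` (monotone decelerating rise
  toward present).  Centred 200-yr rates stay inside the observed
  Holocene envelope of −7.7 to 15.2 mm/yr.
* Index-point databases whose tendencies are drawn Bernoulli from a
  known monotone truth curve of the RSLR rate, with a small no-tendency
  class and an erosional-contact contamination fraction, and with ages
  concentrated in the mid-Holocene (3000–8000 cal BP) as in the real
  database.
* Decadal Monte Carlo projection ensembles: linear background land
  motion plus a stochastic quadratic climate term, calibrated to a
  target 5–95% range of sea-level rise at 2100.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from marshrisk.database_io import IndexPoint, IndexPointDB
from marshrisk.gia_rates import RSLCurve, compute_rate
from marshrisk.projection_coupling import ProjectionEnsemble

REGIMES = ("near_field", "margin", "far_field")

# Holocene RSLR-rate envelopes by loading regime (mm/yr)
NEAR_FIELD_ENVELOPE = (-7.7, 6.0)
FAR_FIELD_EARLY = (3.1, 15.2)
FAR_FIELD_LATE = (0.0, 4.6)

AGE_GRID = np.arange(0.0, 12_001.0, 1000.0)  # cal yr BP, native GIA resolution


@dataclass(frozen=True)
class RegimeParams:
    """Shape parameters for one GIA loading regime's RSL curve."""

    regime: str
    highstand_amplitude_m: float = 2.0  # interior maximum above present
    highstand_age: float = 4000.0  # cal yr BP
    early_rate_mm_yr: float = 10.0  # far-field early-Holocene rise
    present_rate_mm_yr: float = 0.6  # late-Holocene / land-motion rate

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "far_field":
            lo, hi = FAR_FIELD_EARLY
            if not (lo < self.early_rate_mm_yr <= hi):
                raise ValueError(
                    f"far-field early rate {self.early_rate_mm_yr} outside ({lo}, {hi}]"
                )
            if not (FAR_FIELD_LATE[0] <= self.present_rate_mm_yr <= FAR_FIELD_LATE[1]):
                raise ValueError("far-field late rate outside envelope")
        else:
            if not 0.0 < self.highstand_amplitude_m <= 8.0:
                raise ValueError("highstand amplitude must be in (0, 8] m")
            if not NEAR_FIELD_ENVELOPE[0] <= self.early_rate_mm_yr < 0.0:
                raise ValueError(
                    "near-field/margin early-Holocene rate must be a fall "
                    f"within [{NEAR_FIELD_ENVELOPE[0]}, 0)"
                )

    @classmethod
    def default(cls, regime: str) -> "RegimeParams":
        if regime == "near_field":
            return cls(regime, highstand_amplitude_m=2.0, highstand_age=4000.0,
                       early_rate_mm_yr=-4.0, present_rate_mm_yr=-0.5)
        if regime == "margin":
            return cls(regime, highstand_amplitude_m=0.5, highstand_age=4000.0,
                       early_rate_mm_yr=-1.5, present_rate_mm_yr=-0.2)
        if regime == "far_field":
            return cls(regime, early_rate_mm_yr=10.0, present_rate_mm_yr=0.6)
        raise ValueError(f"unknown regime {regime!r}")


@dataclass(frozen=True)
class TruthCurve:
    """Known monotone truth for the retreat probability vs RSLR rate.

    Default logistic(−1.5 + 0.5·x): p ≈ 0.9 near +7 mm/yr and ≈ 0.1 near
    −2 mm/yr, echoing the shape of the fitted Holocene curve.
    """

    form: str = "logistic"
    intercept: float = -1.5
    slope: float = 0.5

    def __post_init__(self) -> None:
        if self.form != "logistic":
            raise ValueError("only the logistic form is implemented")
        if self.slope < 0:
            raise ValueError("truth curve must be monotone non-decreasing")

    def __call__(self, rate) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(rate, dtype=float))

    def inverse(self, p: float) -> float:
        """Rate at which the truth curve attains probability ``p``."""
        if self.slope == 0:
            raise ValueError("flat truth curve has no inverse")
        return float((logit(p) - self.intercept) / self.slope)


def _segment_rates(params: RegimeParams, rng: np.random.Generator) -> np.ndarray:
    """Per-millennium RSLR rates (mm/yr), index 0 = youngest segment."""
    n_seg = len(AGE_GRID) - 1
    if params.regime == "far_field":
        # decelerating monotone rise: late-Holocene rate up to the early cap
        frac = (np.arange(n_seg) / (n_seg - 1)) ** 2
        rates = params.present_rate_mm_yr + frac * (
            params.early_rate_mm_yr - params.present_rate_mm_yr
        )
        rates *= 1.0 + 0.05 * rng.uniform(-1.0, 1.0, n_seg)
        return np.clip(rates, 0.0, FAR_FIELD_EARLY[1])
    # near-field / margin: late fall, mid rise, early deglacial fall
    n_late = int(params.highstand_age // 1000)
    n_early = 3
    n_mid = n_seg - n_late - n_early
    late = -np.linspace(0.5, 1.5, n_late)
    late *= params.highstand_amplitude_m / -late.sum()  # amplitude = total late fall
    mid_total = 8.0 if params.regime == "near_field" else 3.0
    mid = np.linspace(1.0, 2.0, n_mid)
    mid *= mid_total / mid.sum()
    early = np.linspace(params.early_rate_mm_yr, params.early_rate_mm_yr * 0.5, n_early)
    rates = np.concatenate([late, mid, early])
    rates *= 1.0 + 0.05 * rng.uniform(-1.0, 1.0, n_seg)
    return np.clip(rates, NEAR_FIELD_ENVELOPE[0], NEAR_FIELD_ENVELOPE[1])


def gen_rsl_curve(params: RegimeParams, seed: int, site_id: str | None = None) -> RSLCurve:
    """One RSL curve on the 0–12,000 cal BP grid at 1000-yr resolution.

    The node series integrates a per-millennium rate sequence with
    RSL(0) = 0 (present), so the centred-difference rate recovered by
    :func:`~marshrisk.gia_rates.compute_rate` inside any single segment
    equals the generator's internal slope exactly.
    """
    rng = np.random.default_rng(seed)
    rates = _segment_rates(params, rng)
    # rate (mm/yr) over a 1000-yr segment is numerically metres per segment
    rsl = np.concatenate([[0.0], -np.cumsum(rates)])
    curve = RSLCurve(
        site_id=site_id or f"{params.regime}_{seed}",
        t=AGE_GRID.copy(),
        rsl=rsl,
        native_resolution=1000.0,
    )
    _check_envelope(params.regime, rates)
    return curve


def _check_envelope(regime: str, rates: np.ndarray) -> None:
    if regime == "far_field":
        if rates.min() < FAR_FIELD_LATE[0] - 1e-9 or rates.max() > FAR_FIELD_EARLY[1] + 1e-9:
            raise ValueError("far-field rates escape the Holocene envelope")
    else:
        lo, hi = NEAR_FIELD_ENVELOPE
        if rates.min() < lo - 1e-9 or rates.max() > hi + 1e-9:
            raise ValueError(f"{regime} rates escape the Holocene envelope")


def default_curve_set(seed: int, n_per_regime: int = 3) -> dict[str, RSLCurve]:
    """A small multi-regime curve collection keyed by site id."""
    rng = np.random.default_rng(seed)
    curves: dict[str, RSLCurve] = {}
    for regime in REGIMES:
        for i in range(n_per_regime):
            sid = f"{regime}_{i}"
            curves[sid] = gen_rsl_curve(
                RegimeParams.default(regime), int(rng.integers(0, 2**31 - 1)), site_id=sid
            )
    return curves


def gen_index_points(
    curves: Mapping[str, RSLCurve],
    truth: TruthCurve,
    n: int,
    frac_none: float = 0.017,
    frac_erosional: float = 0.288,
    seed: int = 0,
) -> tuple[IndexPointDB, pd.DataFrame]:
    """Index points with tendencies drawn from the truth curve.

    Ages concentrate in the mid-Holocene (3000–8000 cal BP, ~65% of
    points) with the remainder uniform over the record, mirroring the
    temporal distribution of the real database; each point's tendency is
    Bernoulli(truth(rate)) for positive vs negative, after which a
    ``frac_none`` share is relabelled ``none`` and a ``frac_erosional``
    share is marked erosional.  The default fractions reproduce the
    printed composition of the observational database (19/1097 no
    tendency; 316/1097 erosional).

    Returns the database plus a parallel truth table (point_id, rate,
    p_true, y_true) for recovery tests.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= frac_none < 1 and 0 <= frac_erosional < 1):
        raise ValueError("fractions must be in [0, 1)")
    if not curves:
        raise ValueError("need at least one RSL curve")
    rng = np.random.default_rng(seed)
    site_ids = sorted(curves)

    mid = rng.random(n) < 0.65
    ages = np.where(
        mid,
        rng.normal(5500.0, 1300.0, n),
        rng.uniform(300.0, 11_700.0, n),
    )
    ages = np.clip(ages, 150.0, 11_850.0)  # keep the ±100 yr window in support
    regions = rng.choice(site_ids, size=n)

    rates = np.array(
        [compute_rate(curves[r], a) for r, a in zip(regions, ages)], dtype=float
    )
    p_true = truth(rates)
    y_true = (rng.random(n) < p_true).astype(int)
    tendency = np.where(y_true == 1, "positive", "negative").astype(object)
    tendency[rng.random(n) < frac_none] = "none"
    contact = np.where(rng.random(n) < frac_erosional, "erosional", "gradual")

    coords = {s: (50.0 + 8.0 * i / max(len(site_ids) - 1, 1), -6.0 + 0.15 * i)
              for i, s in enumerate(site_ids)}
    points = []
    for i in range(n):
        lat, lon = coords[regions[i]]
        points.append(
            IndexPoint(
                point_id=f"sp{i:05d}",
                region_id=str(regions[i]),
                lat=lat + float(rng.normal(0, 0.05)),
                lon=lon + float(rng.normal(0, 0.05)),
                age=float(ages[i]),
                tendency=str(tendency[i]),
                contact=str(contact[i]),
            )
        )
    db = IndexPointDB(points, source=f"<synthetic seed={seed}>")
    truth_table = pd.DataFrame(
        {
            "point_id": [p.point_id for p in points],
            "rate_mm_yr": rates,
            "p_true": p_true,
            "y_true": y_true,
        }
    )
    return db, truth_table


def default_recovery_dataset(seed: int, n: int = 800, truth: TruthCurve | None = None):
    """The standard parameter-recovery dataset: clean two-class points.

    Generates multi-regime curves and ``n`` gradual-contact points with
    tendencies drawn from the (default logistic) truth curve, with no
    no-tendency or erosional contamination, and returns
    ``(TendencyDataset, truth, truth_table)`` ready for fitting.
    """
    from marshrisk.database_io import encode_tendencies

    truth = truth or TruthCurve()
    rng = np.random.default_rng(seed)
    curves = default_curve_set(int(rng.integers(0, 2**31 - 1)))
    db, table = gen_index_points(
        curves, truth, n=n, frac_none=0.0, frac_erosional=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    data = encode_tendencies(db, table["rate_mm_yr"].to_numpy())
    return data, truth, table


@dataclass(frozen=True)
class ScenarioParams:
    """Stylized projection-ensemble scenario.

    ``rise_2100_cm`` is the target 5th–95th percentile range of sea-level
    rise between 2000 and 2100 (e.g. (23, 123) for a Thames-estuary-like
    site under a high-emission pathway).  Equal targets give a
    deterministic (zero-spread) ensemble.
    """

    site_id: str = "tilbury_like"
    scenario: str = "RCP8.5"
    rise_2100_cm: tuple[float, float] = (23.0, 123.0)
    background_rate_mm_yr: float = 0.8  # land motion; subsidence positive
    n_samples: int = 10_000
    year_start: int = 2000
    year_end: int = 2300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rise_2100_cm[0] > self.rise_2100_cm[1]:
            raise ValueError("5% target must not exceed 95% target")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")


_Z90 = 1.6448536269514722  # standard-normal 95th percentile


def gen_projection_ensemble(params: ScenarioParams) -> ProjectionEnsemble:
    """Monte Carlo decadal RSL ensemble calibrated to a 2100 rise target.

    Each trajectory is a linear background (land motion) plus a quadratic
    climate term: rsl(t) = v·(t−2000)/10 + a·((t−2000)/100)² cm, with the
    per-sample acceleration ``a`` drawn normal and then affinely
    recalibrated so the realized 5th–95th percentile of the 2100 rise
    matches ``rise_2100_cm``.
    """
    years = np.arange(params.year_start, params.year_end + 1, 10, dtype=float)
    rng = np.random.default_rng(params.seed)
    q5, q95 = params.rise_2100_cm
    background_2100 = params.background_rate_mm_yr * 100.0 / 10.0  # cm over a century

    if q95 > q5 and params.n_samples > 1:
        mu = 0.5 * (q5 + q95)
        sd = (q95 - q5) / (2.0 * _Z90)
        rise = rng.normal(mu, sd, params.n_samples)
        r5, r95 = np.percentile(rise, [5.0, 95.0])
        if not r95 > r5:
            raise ValueError("degenerate sample spread; cannot calibrate to target range")
        rise = q5 + (rise - r5) * (q95 - q5) / (r95 - r5)  # realized quantiles -> target
    else:
        rise = np.full(params.n_samples, 0.5 * (q5 + q95))
    accel = rise - background_2100  # quadratic coefficient, cm at 2100

    tau = (years - params.year_start) / 100.0
    linear = params.background_rate_mm_yr * (years - params.year_start) / 10.0
    samples = linear[None, :] + accel[:, None] * tau[None, :] ** 2
    return ProjectionEnsemble(
        site_id=params.site_id,
        scenario=params.scenario,
        years=years,
        samples=samples,
    )
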