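"""Couple retreat-probability curves with sea-level projection ensembles.

For each Monte Carlo sample trajectory of future relative sea level:
take the trailing 20-year average rate of change on the decadal grid,
its running (cumulative) maximum, and the posterior-mean retreat
probability at that maximal rate; then average the probabilities across
samples.  The cumulative maximum composed with a monotone probability
curve makes every timeline non-decreasing in time, so the first year at
which the expected probability strictly exceeds a threshold (default
0.8) dates the onset of likely marsh retreat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from marshrisk.monotone_pspline import ProbabilityCurve

NOT_REACHED = "not reached"

CM_PER_YR_TO_MM_PER_YR = 10.0
RATE_WINDOW_YR = 20.0


@dataclass
class ProjectionEnsemble:
    """Monte Carlo future RSL samples for one site and scenario.

    ``samples`` holds RSL in cm relative to the year-2000 baseline, one
    row per Monte Carlo sample, columns on the decadal ``years`` grid
    (calendar years CE, constant 10-yr step).
    """

    site_id: str
    scenario: str
    years: np.ndarray
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        steps = np.diff(self.years)
        if len(steps) < 2 or not np.allclose(steps, 10.0):
            raise ValueError("years must be a decadal grid (constant 10-yr step, >= 3 points)")
        if self.samples.shape[1] != self.years.size:
            raise ValueError("samples columns must match years grid")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class RetreatTimeline:
    """Expected retreat probability per year with threshold-crossing year."""

    site_id: str
    scenario: str
    years: np.ndarray  # evaluable years (first two decades have no 20-yr rate)
    probability: np.ndarray
    threshold: float = 0.8
    threshold_year: float | str = NOT_REACHED

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "scenario": self.scenario,
                "year": self.years.astype(int),
                "probability": self.probability,
            }
        )


def twenty_year_rates(sample: Sequence[float], years: Sequence[float]) -> np.ndarray:
    """Trailing 20-year average rates (mm/yr) on a decadal grid.

    rate(t) = (RSL(t) − RSL(t−20)) / 20 with cm→mm conversion; the first
    two decades have no lookback and yield no value, so the result aligns
    with ``years[2:]``.
    """
    years = np.asarray(years, dtype=float)
    sample = np.asarray(sample, dtype=float)
    steps = np.diff(years)
    if len(steps) < 2 or not np.allclose(steps, 10.0):
        raise ValueError("years must be a decadal grid (constant 10-yr step, >= 3 points)")
    return (sample[2:] - sample[:-2]) / RATE_WINDOW_YR * CM_PER_YR_TO_MM_PER_YR


def cumulative_max(series: Sequence[float]) -> np.ndarray:
    """Running maximum: out[i] = max(series[0..i])."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series must be non-empty")
    return np.maximum.accumulate(series)


def retreat_timeline(
    post_curve: ProbabilityCurve,
    ens: ProjectionEnsemble,
    threshold: float = 0.8,
) -> RetreatTimeline:
    """Expected retreat probability per year for one projection ensemble.

    Per sample: 20-yr rates → cumulative maximum → probability via the
    posterior-mean curve (flat beyond its support); then the arithmetic
    mean across samples.  ``threshold_year`` is the first year whose
    probability strictly exceeds ``threshold`` on the decadal grid.
    """
    if ens.n_samples == 0:
        raise ValueError("ensemble has no samples")
    rates = (ens.samples[:, 2:] - ens.samples[:, :-2]) / RATE_WINDOW_YR * CM_PER_YR_TO_MM_PER_YR
    running_max = np.maximum.accumulate(rates, axis=1)
    prob = post_curve.evaluate(running_max.ravel()).reshape(running_max.shape)
    expected = prob.mean(axis=0)
    years = ens.years[2:]
    crossing = np.nonzero(expected > threshold)[0]
    threshold_year: float | str = float(years[crossing[0]]) if crossing.size else NOT_REACHED
    return RetreatTimeline(
        site_id=ens.site_id,
        scenario=ens.scenario,
        years=years,
        probability=expected,
        threshold=threshold,
        threshold_year=threshold_year,
    )


def threshold_year_table(timelines: Iterable[RetreatTimeline]) -> pd.DataFrame:
    """One row per site × scenario with the threshold-crossing year.

    "not reached" is preserved as a distinct value.  All timelines must
    share the same threshold.
    """
    timelines = list(timelines)
    thresholds = {t.threshold for t in timelines}
    if len(thresholds) > 1:
        raise ValueError(f"mixed thresholds: {sorted(thresholds)}")
    return pd.DataFrame(
        {
            "site_id": [t.site_id for t in timelines],
            "scenario": [t.scenario for t in timelines],
            "threshold": [t.threshold for t in timelines],
            "year": [t.threshold_year for t in timelines],
        }
    )


# --------------------------------------------------------------------------
# file formats


def read_projection_ensembles(path) -> list[ProjectionEnsemble]:
    """Read ensembles from columns site_id,scenario,sample_id,year,rsl_cm."""
    frame = pd.read_csv(path)
    required = {"site_id", "scenario", "sample_id", "year", "rsl_cm"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    out = []
    for (site, scen), grp in frame.groupby(["site_id", "scenario"], sort=False):
        wide = grp.pivot_table(index="sample_id", columns="year", values="rsl_cm", sort=True)
        if wide.isna().any().any():
            raise ValueError(f"{path}: ragged ensemble for {site}/{scen}")
        out.append(
            ProjectionEnsemble(
                site_id=str(site),
                scenario=str(scen),
                years=wide.columns.to_numpy(dtype=float),
                samples=wide.to_numpy(dtype=float),
            )
        )
    return out


def write_projection_ensemble(ens: ProjectionEnsemble, path, *, mode: str = "w") -> None:
    frames = pd.DataFrame(ens.samples, columns=ens.years.astype(int))
    frames.insert(0, "sample_id", np.arange(ens.n_samples))
    long = frames.melt(id_vars="sample_id", var_name="year", value_name="rsl_cm")
    long.insert(0, "site_id", ens.site_id)
    long.insert(1, "scenario", ens.scenario)
    long.sort_values(["sample_id", "year"]).to_csv(
        path, index=False, mode=mode, header=(mode == "w")
    )


def write_timelines(timelines: Iterable[RetreatTimeline], path) -> None:
    pd.concat([t.to_frame() for t in timelines], ignore_index=True).to_csv(path, index=False)
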