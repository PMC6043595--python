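"""RSLR rate assignment from glacio-isostatic relative sea-level curves.

Relative sea-level (RSL) predictions from a glacial isostatic adjustment
model arrive as coarse node series (native resolution ~1000 yr).  The
rate of relative sea-level rise (RSLR) assigned to an index point is the
centred 200-yr (±100 yr) finite difference of the piecewise-linearly
interpolated curve at the point's median calibrated age.

Sign convention: rate > 0 means RSL *rising* toward the present, i.e.
RSL is higher at the younger end of the window (smaller cal BP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from marshrisk.database_io import IndexPointDB

M_PER_YR_TO_MM_PER_YR = 1000.0


class OutOfRangeError(ValueError):
    """Requested age (or differencing window) leaves the curve support."""


@dataclass
class RSLCurve:
    """Per-site RSL(t) node series, metres relative to present.

    ``t`` is in years cal BP and must be strictly increasing; the curve is
    interpreted piecewise-linearly between nodes with no extrapolation.
    """

    site_id: str
    t: np.ndarray
    rsl: np.ndarray
    native_resolution: float | None = 1000.0  # yr between nodes, metadata

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rsl = np.asarray(self.rsl, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("curve needs at least 2 nodes")
        if self.rsl.shape != self.t.shape:
            raise ValueError("t and rsl must be parallel")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.rsl)):
            raise ValueError("rsl must be finite")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


@dataclass(frozen=True)
class RateEstimate:
    """RSLR rate assigned to one index point."""

    point_id: str
    rate: float  # mm/yr, positive = rise toward present
    window_half_width: float = 100.0  # yr
    in_support: bool = True


def interpolate_rsl(curve: RSLCurve, age: float) -> float:
    """Piecewise-linear RSL (m) at ``age`` cal BP; exact at nodes."""
    lo, hi = curve.support
    if not (lo <= age <= hi):
        raise OutOfRangeError(
            f"age {age} cal BP outside curve support [{lo:g}, {hi:g}] for site {curve.site_id}"
        )
    return float(np.interp(age, curve.t, curve.rsl))


def compute_rate(curve: RSLCurve, age: float, half_width: float = 100.0) -> float:
    """Centred-difference RSLR rate (mm/yr) over ``age ± half_width``.

    rate = (RSL(age − h) − RSL(age + h)) / (2 h), scaled to mm/yr: the
    younger (smaller cal BP) end comes first, so a curve rising toward the
    present gives a positive rate.  Exact on windows lying inside a single
    linear segment, where it equals the segment slope.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    lo, hi = curve.support
    young, old = age - half_width, age + half_width
    if young < lo:
        raise OutOfRangeError(
            f"window bound {young:g} cal BP below curve support {lo:g} (site {curve.site_id})"
        )
    if old > hi:
        raise OutOfRangeError(
            f"window bound {old:g} cal BP above curve support {hi:g} (site {curve.site_id})"
        )
    dm = interpolate_rsl(curve, young) - interpolate_rsl(curve, old)
    return dm / (2.0 * half_width) * M_PER_YR_TO_MM_PER_YR


def assign_rates(
    db: IndexPointDB,
    curves: Mapping[str, RSLCurve],
    half_width: float = 100.0,
    *,
    on_out_of_range: str = "raise",
) -> list[RateEstimate]:
    """One :class:`RateEstimate` per index point, in database order.

    Each point's ``region_id`` selects its curve.  Points whose centred
    window leaves the curve support are an error by default; with
    ``on_out_of_range="flag"`` they are returned with ``in_support=False``
    and a NaN rate so the caller can drop them explicitly.
    """
    if on_out_of_range not in ("raise", "flag"):
        raise ValueError("on_out_of_range must be 'raise' or 'flag'")
    missing = sorted({p.region_id for p in db.points} - set(curves))
    if missing:
        raise KeyError(f"no RSL curve for region(s): {missing}")
    out: list[RateEstimate] = []
    for p in db.points:
        try:
            r = compute_rate(curves[p.region_id], p.age, half_width)
        except OutOfRangeError:
            if on_out_of_range == "raise":
                raise
            out.append(RateEstimate(p.point_id, float("nan"), half_width, in_support=False))
            continue
        out.append(RateEstimate(p.point_id, r, half_width))
    return out


def read_rsl_curves(path, *, native_resolution: float | None = 1000.0) -> dict[str, RSLCurve]:
    """Read curves from a delimited file with columns site_id,age_cal_bp,rsl_m."""
    frame = pd.read_csv(path)
    required = {"site_id", "age_cal_bp", "rsl_m"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    curves: dict[str, RSLCurve] = {}
    for site, grp in frame.groupby("site_id", sort=False):
        grp = grp.sort_values("age_cal_bp")
        curves[str(site)] = RSLCurve(
            site_id=str(site),
            t=grp["age_cal_bp"].to_numpy(dtype=float),
            rsl=grp["rsl_m"].to_numpy(dtype=float),
            native_resolution=native_resolution,
        )
    return curves


def write_rsl_curves(curves: Mapping[str, RSLCurve] | Sequence[RSLCurve], path) -> None:
    if isinstance(curves, Mapping):
        curves = list(curves.values())
    rows = []
    for c in curves:
        for t, z in zip(c.t, c.rsl):
            rows.append({"site_id": c.site_id, "age_cal_bp": t, "rsl_m": z})
    pd.DataFrame(rows).to_csv(path, index=False)
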