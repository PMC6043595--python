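"""Reading, validating, filtering and encoding index-point databases.

A *sea-level index point* is a dated stratigraphic contact constraining
past relative sea level at a known time and place.  Each point carries a
*tendency* — the direction of change in marine influence it records:

``positive``
    transgressive contact (tidal flat over marsh): marsh retreat.
``negative``
    regressive contact (marsh over tidal flat): marsh expansion.
``none``
    marsh deposit keeping pace with sea level: stable.

and a *contact* quality: ``gradual`` contacts date the transition itself;
``erosional`` contacts only bound it (unknown hiatus) and are excluded
from modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TENDENCIES = ("positive", "negative", "none")
CONTACTS = ("gradual", "erosional")

AGE_MIN = 0.0
AGE_MAX = 12_000.0  # cal yr BP; span of the Holocene database

REQUIRED_COLUMNS = (
    "point_id",
    "region_id",
    "lat",
    "lon",
    "age_cal_bp",
    "tendency",
    "contact",
)


class SchemaError(ValueError):
    """Input file does not match the declared schema."""


@dataclass(frozen=True)
class IndexPoint:
    """One dated stratigraphic contact with its tendency label."""

    point_id: str
    region_id: str
    lat: float
    lon: float
    age: float  # median calibrated age, cal yr BP
    tendency: str  # positive | negative | none
    contact: str  # gradual | erosional
    lithology_note: str | None = None

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise ValueError(
                f"age {self.age} cal BP outside [{AGE_MIN:g}, {AGE_MAX:g}]"
            )
        if self.tendency not in TENDENCIES:
            raise ValueError(f"unknown tendency label {self.tendency!r}")
        if self.contact not in CONTACTS:
            raise ValueError(f"unknown contact label {self.contact!r}")


@dataclass(frozen=True)
class FilterRecord:
    """One excluded point with a machine-parseable reason code."""

    point_id: str
    reason: str


@dataclass
class IndexPointDB:
    """Ordered collection of index points with filter provenance."""

    points: list[IndexPoint]
    source: str = "<memory>"
    filter_log: list[FilterRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.point_id for p in self.points]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate point_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def ages(self) -> np.ndarray:
        return np.array([p.age for p in self.points], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "point_id": [p.point_id for p in self.points],
                "region_id": [p.region_id for p in self.points],
                "lat": [p.lat for p in self.points],
                "lon": [p.lon for p in self.points],
                "age_cal_bp": [p.age for p in self.points],
                "tendency": [p.tendency for p in self.points],
                "contact": [p.contact for p in self.points],
            }
        )

    def write_filter_log(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.filter_log:
                fh.write(f"{rec.point_id}\t{rec.reason}\n")


@dataclass
class TendencyDataset:
    """Paired (RSLR rate x_i, binary response y_i) vectors for the model."""

    x: np.ndarray  # rates, mm/yr
    y: np.ndarray  # 0/1: 1 = positive tendency (retreat)
    point_ids: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.x) == len(self.y) == len(self.point_ids)):
            raise ValueError("x, y, point_ids must have equal length")
        if len(self.x) and not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite rate in x")
        if len(self.y) and not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be strictly in {0, 1}")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class Dialect:
    """Mapping from a file's column names and labels onto the canonical schema.

    ``columns`` maps canonical name -> file column name; ``tendency_map``
    and ``contact_map`` translate file labels (case-insensitive) onto the
    canonical vocabularies.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    tendency_map: Mapping[str, str] = field(default_factory=dict)
    contact_map: Mapping[str, str] = field(default_factory=dict)
    delimiter: str = ","

    def column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def map_tendency(self, raw: str) -> str:
        raw = raw.strip()
        return self.tendency_map.get(raw, self.tendency_map.get(raw.lower(), raw.lower()))

    def map_contact(self, raw: str) -> str:
        raw = raw.strip()
        return self.contact_map.get(raw, self.contact_map.get(raw.lower(), raw.lower()))


@dataclass
class RowError:
    line: int  # 1-based line number in the file (header = 1)
    message: str


def read_index_points(
    path, dialect: Dialect | None = None, *, strict: bool = True
) -> tuple[IndexPointDB, list[RowError]]:
    """Read a delimited index-point file into an :class:`IndexPointDB`.

    Every row either becomes an :class:`IndexPoint` or is reported in the
    returned error list with its line number — rows are never dropped
    silently.  With ``strict=True`` (default) any row error raises.
    """
    dialect = dialect or Dialect()
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in REQUIRED_COLUMNS if dialect.column(c) not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    points: list[IndexPoint] = []
    errors: list[RowError] = []
    for idx, row in raw.iterrows():
        line = int(idx) + 2  # header occupies line 1
        try:
            point = IndexPoint(
                point_id=str(row[dialect.column("point_id")]),
                region_id=str(row[dialect.column("region_id")]),
                lat=float(row[dialect.column("lat")]),
                lon=float(row[dialect.column("lon")]),
                age=float(row[dialect.column("age_cal_bp")]),
                tendency=dialect.map_tendency(str(row[dialect.column("tendency")])),
                contact=dialect.map_contact(str(row[dialect.column("contact")])),
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(line=line, message=str(exc)))
            continue
        points.append(point)
    if strict and errors:
        detail = "; ".join(f"line {e.line}: {e.message}" for e in errors[:5])
        raise ValueError(f"{path}: {len(errors)} bad row(s): {detail}")
    return IndexPointDB(points, source=str(path)), errors


def write_index_points(db: IndexPointDB, path) -> None:
    db.to_frame().to_csv(path, index=False)


def filter_gradual(db: IndexPointDB) -> IndexPointDB:
    """Keep only gradual-contact points; log each erosional exclusion.

    Erosional contacts give only a minimum age for the transition (the
    hiatus duration is unknown), so they cannot be paired with a rate.
    Idempotent.
    """
    kept = [p for p in db.points if p.contact == "gradual"]
    dropped = [FilterRecord(p.point_id, "erosional") for p in db.points if p.contact != "gradual"]
    return IndexPointDB(kept, source=db.source, filter_log=list(db.filter_log) + dropped)


def encode_tendencies(
    db: IndexPointDB,
    rates: Sequence[float],
    *,
    none_as_zero: bool = True,
) -> TendencyDataset:
    """Encode tendencies as the binary response paired with RSLR rates.

    Default coding: positive tendency -> 1, negative and no tendency -> 0.
    With ``none_as_zero=False`` the no-tendency points are dropped instead
    (the stricter two-class coding); their rates are dropped in parallel.
    """
    rates = np.asarray(rates, dtype=float)
    if len(rates) != len(db):
        raise ValueError(f"{len(rates)} rates for {len(db)} points")
    xs, ys, ids = [], [], []
    for point, rate in zip(db.points, rates):
        if point.tendency == "none" and not none_as_zero:
            continue
        xs.append(rate)
        ys.append(1 if point.tendency == "positive" else 0)
        ids.append(point.point_id)
    return TendencyDataset(np.array(xs, dtype=float), np.array(ys, dtype=int), ids)


def tendency_proportions(
    db: IndexPointDB, rates: Sequence[float], bin_width: float = 0.5
) -> pd.DataFrame:
    """Per-bin counts and proportions of each tendency class.

    Rates are binned into half-open intervals ``[a, a + bin_width)``
    anchored at integer multiples of ``bin_width``.  Returns a frame with
    one row per occupied bin: ``bin_left_edge``, ``n_<class>`` counts,
    ``p_<class>`` within-bin proportions, and ``n_total``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rates = np.asarray(rates, dtype=float)
    if len(rates) != len(db):
        raise ValueError(f"{len(rates)} rates for {len(db)} points")
    cols = ["bin_left_edge"]
    cols += [f"n_{t}" for t in TENDENCIES] + [f"p_{t}" for t in TENDENCIES] + ["n_total"]
    if len(db) == 0:
        return pd.DataFrame(columns=cols)
    left = np.floor(rates / bin_width) * bin_width
    frame = pd.DataFrame({"left": left, "tendency": [p.tendency for p in db.points]})
    out_rows = []
    for edge, grp in frame.groupby("left", sort=True):
        counts = {t: int((grp["tendency"] == t).sum()) for t in TENDENCIES}
        total = sum(counts.values())
        row: dict[str, float] = {"bin_left_edge": float(edge), "n_total": total}
        for t in TENDENCIES:
            row[f"n_{t}"] = counts[t]
            row[f"p_{t}"] = counts[t] / total if total else np.nan
        out_rows.append(row)
    return pd.DataFrame(out_rows, columns=cols)
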