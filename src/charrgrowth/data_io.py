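"""Data model and tabular I/O for the cave capture-mark-recapture design.

The study design is a grid of semi-annual capture occasions (June and August
of each study year).  Consecutive occasions bound two kinds of growth
interval: June -> August ("summer", nominally 16 June - 22 August, 67 days)
and August -> June ("winter", nominally 22 August - 16 June of the following
year, 298 or 299 days).  Fish are identified individuals inside discrete
caves; seasonal mean water temperature is recorded per cave x interval cell
and may be missing.

All files are UTF-8 comma-separated with a header row; a missing value is an
empty field.  This single dialect guarantees bit-exact round trips.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUMMER = "summer"
WINTER = "winter"
SEASONS = (SUMMER, WINTER)

JUNE = "June"
AUGUST = "August"
#: nominal mid-dates of the two field visits, shared across years
NOMINAL_DAY = {JUNE: (6, 16), AUGUST: (8, 22)}

#: months each season spans when converting monthly rates to seasonal totals
SEASON_MONTHS = {SUMMER: 2, WINTER: 10}


class DataError(ValueError):
    """Raised when an input file or record set violates the data contract."""


@dataclass(frozen=True)
class Occasion:
    """One capture occasion: a (year, month) cell of the sampling grid."""

    index: int
    year: int
    month_tag: str

    def __post_init__(self):
        if self.month_tag not in (JUNE, AUGUST):
            raise DataError(f"unknown month tag {self.month_tag!r}")

    @property
    def nominal_date(self) -> dt.date:
        month, day = NOMINAL_DAY[self.month_tag]
        return dt.date(self.year, month, day)


@dataclass(frozen=True)
class SeasonInterval:
    """The transition between two consecutive occasions."""

    from_occasion: int
    to_occasion: int
    season: str
    n_days: int
    #: the interval's year label; a winter starting August y is labelled y
    year: int

    @property
    def n_months(self) -> int:
        return SEASON_MONTHS[self.season]


@dataclass(frozen=True)
class CaptureRecord:
    fish_id: str
    cave_id: str
    occasion: int
    fork_length_mm: float
    capture_date: dt.date | None = None


@dataclass(frozen=True)
class TemperatureRecord:
    cave_id: str
    year: int
    season: str
    mean_temp_C: float | None  # None encodes a missing cell


@dataclass(frozen=True)
class RepeatMeasureRecord:
    fish_id: str
    measurements: tuple[float, ...]

    def __post_init__(self):
        if len(self.measurements) < 2:
            raise DataError(f"fish {self.fish_id}: need >= 2 repeat measurements")
        if any(m <= 0 for m in self.measurements):
            raise DataError(f"fish {self.fish_id}: non-positive measurement")


def interval_days(from_date: dt.date, to_date: dt.date) -> int:
    """Exact calendar-day span between two dates (leap years honoured)."""
    days = (to_date - from_date).days
    if days <= 0:
        raise DataError(f"non-positive interval {from_date} -> {to_date}")
    return days


def season_of(from_month: str, to_month: str) -> str:
    if (from_month, to_month) == (JUNE, AUGUST):
        return SUMMER
    if (from_month, to_month) == (AUGUST, JUNE):
        return WINTER
    raise DataError(f"occasions {from_month} -> {to_month} do not form a season")


def build_occasion_grid(year_month_pairs: Iterable[tuple[int, str]]) -> list[Occasion]:
    """Sorted, validated occasion grid from distinct (year, month) pairs."""
    order = {JUNE: 0, AUGUST: 1}
    pairs = sorted(set(year_month_pairs), key=lambda p: (p[0], order[p[1]]))
    occasions = [Occasion(i, y, m) for i, (y, m) in enumerate(pairs)]
    for a, b in zip(occasions, occasions[1:]):
        if a.month_tag == b.month_tag:
            raise DataError(
                f"occasion months do not alternate June/August: "
                f"{a.year} {a.month_tag} followed by {b.year} {b.month_tag}"
            )
        season_of(a.month_tag, b.month_tag)  # validates the transition
    return occasions


def season_intervals(occasions: Sequence[Occasion]) -> list[SeasonInterval]:
    out = []
    for a, b in zip(occasions, occasions[1:]):
        out.append(
            SeasonInterval(
                from_occasion=a.index,
                to_occasion=b.index,
                season=season_of(a.month_tag, b.month_tag),
                n_days=interval_days(a.nominal_date, b.nominal_date),
                year=a.year,
            )
        )
    return out


# ---------------------------------------------------------------------------
# file readers / writers


def read_captures(
    path: str | Path,
    plausibility_window: tuple[float, float] = (30.0, 300.0),
) -> tuple[list[CaptureRecord], list[Occasion]]:
    """Read captures.csv and infer the occasion grid.

    Columns: fish_id, cave_id, year, month (June|August), fork_length_mm,
    capture_date (ISO-8601, optional column / optional per row).
    """
    df = pd.read_csv(path, dtype={"fish_id": str, "cave_id": str}, float_precision="round_trip")
    required = {"fish_id", "cave_id", "year", "month", "fork_length_mm"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise DataError(f"{path}: missing columns {sorted(missing_cols)}")
    bad_month = ~df["month"].isin([JUNE, AUGUST])
    if bad_month.any():
        raise DataError(
            f"{path}: unknown month tag(s) {sorted(df.loc[bad_month, 'month'].unique())}"
        )
    lo, hi = plausibility_window
    bad_len = (df["fork_length_mm"] < lo) | (df["fork_length_mm"] > hi)
    if bad_len.any():
        rows = (df.index[bad_len] + 2).tolist()  # 1-based incl. header
        raise DataError(
            f"{path}: fork lengths outside [{lo}, {hi}] mm at file rows {rows}"
        )
    occasions = build_occasion_grid(
        (int(y), str(m)) for y, m in zip(df["year"], df["month"])
    )
    occ_index = {(o.year, o.month_tag): o.index for o in occasions}
    dup = df.duplicated(subset=["fish_id", "year", "month"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise DataError(
            f"{path}: duplicate capture for fish {first['fish_id']} at "
            f"{first['month']} {first['year']}"
        )
    caves = df.groupby("fish_id")["cave_id"].nunique()
    roaming = caves[caves > 1]
    if not roaming.empty:
        raise DataError(f"{path}: fish recorded in multiple caves: {list(roaming.index)}")
    have_dates = "capture_date" in df.columns
    records = []
    for row in df.itertuples(index=False):
        date = None
        if have_dates and isinstance(row.capture_date, str) and row.capture_date:
            date = dt.date.fromisoformat(row.capture_date)
        records.append(
            CaptureRecord(
                fish_id=str(row.fish_id),
                cave_id=str(row.cave_id),
                occasion=occ_index[(int(row.year), row.month)],
                fork_length_mm=float(row.fork_length_mm),
                capture_date=date,
            )
        )
    return records, occasions


def write_captures(
    path: str | Path, records: Sequence[CaptureRecord], occasions: Sequence[Occasion]
) -> None:
    rows = []
    for r in records:
        occ = occasions[r.occasion]
        rows.append(
            {
                "fish_id": r.fish_id,
                "cave_id": r.cave_id,
                "year": occ.year,
                "month": occ.month_tag,
                # shortest round-trip repr so write-then-read is bit exact
                "fork_length_mm": repr(float(r.fork_length_mm)),
                "capture_date": r.capture_date.isoformat() if r.capture_date else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_temperatures(
    path: str | Path, plausibility_window: tuple[float, float] = (0.0, 20.0)
) -> list[TemperatureRecord]:
    df = pd.read_csv(path, dtype={"cave_id": str}, float_precision="round_trip")
    required = {"cave_id", "year", "season", "mean_temp_C"}
    if required - set(df.columns):
        raise DataError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad = ~df["season"].isin(SEASONS)
    if bad.any():
        raise DataError(f"{path}: unknown season(s) {sorted(df.loc[bad, 'season'].unique())}")
    if df.duplicated(subset=["cave_id", "year", "season"]).any():
        raise DataError(f"{path}: duplicate cave x year x season cell")
    lo, hi = plausibility_window
    observed = df["mean_temp_C"].notna()
    bad_t = observed & ((df["mean_temp_C"] < lo) | (df["mean_temp_C"] > hi))
    if bad_t.any():
        raise DataError(f"{path}: temperatures outside [{lo}, {hi}] C")
    return [
        TemperatureRecord(
            cave_id=str(r.cave_id),
            year=int(r.year),
            season=str(r.season),
            mean_temp_C=None if pd.isna(r.mean_temp_C) else float(r.mean_temp_C),
        )
        for r in df.itertuples(index=False)
    ]


def write_temperatures(path: str | Path, records: Sequence[TemperatureRecord]) -> None:
    pd.DataFrame(
        {
            "cave_id": [r.cave_id for r in records],
            "year": [r.year for r in records],
            "season": [r.season for r in records],
            "mean_temp_C": [
                "" if r.mean_temp_C is None else repr(float(r.mean_temp_C))
                for r in records
            ],
        }
    ).to_csv(path, index=False)


def read_repeats(path: str | Path) -> list[RepeatMeasureRecord]:
    df = pd.read_csv(path, dtype={"fish_id": str}, float_precision="round_trip")
    required = {"fish_id", "replicate_index", "fork_length_mm"}
    if required - set(df.columns):
        raise DataError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for fish, grp in df.groupby("fish_id", sort=True):
        vals = tuple(
            float(v)
            for v in grp.sort_values("replicate_index")["fork_length_mm"]
        )
        out.append(RepeatMeasureRecord(fish_id=str(fish), measurements=vals))
    return out


def write_repeats(path: str | Path, records: Sequence[RepeatMeasureRecord]) -> None:
    rows = [
        {"fish_id": r.fish_id, "replicate_index": i, "fork_length_mm": repr(float(m))}
        for r in records
        for i, m in enumerate(r.measurements)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# panel construction


@dataclass
class GrowthPanel:
    """Aligned arrays for one cave system, ready for fitting.

    Latent-size support for a fish spans exactly the occasions between its
    first and last capture (there is no survival model, so nothing is said
    about a fish after its last capture).  ``obs`` holds observed fork
    lengths with NaN where a fish was not captured; ``temp`` holds the
    cave x interval temperature grid with NaN for cells to be augmented.
    """

    occasions: list[Occasion]
    intervals: list[SeasonInterval]
    fish_ids: list[str]
    cave_ids: list[str]  # unique cave labels, index order
    fish_cave: np.ndarray  # (F,) cave index per fish
    first: np.ndarray  # (F,) first-capture occasion index
    last: np.ndarray  # (F,)
    obs: np.ndarray  # (F, T) observed lengths, NaN = not captured
    days: np.ndarray  # (F, T-1) interval length in days per fish
    temp: np.ndarray  # (C, T-1) seasonal mean temperature, NaN = missing
    center_size: float
    center_temp: float
    meta: dict = field(default_factory=dict)

    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def n_caves(self) -> int:
        return len(self.cave_ids)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def n_missing_temp(self) -> int:
        return int(np.isnan(self.temp).sum())

    def n_growth_intervals(self) -> int:
        """Total consecutive-occasion transitions across all fish supports."""
        return int((self.last - self.first).sum())

    def fish_index(self, fish_id: str) -> int:
        try:
            return self.fish_ids.index(fish_id)
        except ValueError:
            raise KeyError(f"unknown fish {fish_id!r}") from None

    def drop_observations(self, holdouts: Sequence[tuple[str, int]]) -> "GrowthPanel":
        """Copy of the panel with the given (fish_id, occasion) cells masked.

        Supports are left untouched, so a masked endpoint remains part of the
        fish's latent trajectory and can be predicted.
        """
        obs = self.obs.copy()
        for fish_id, occ in holdouts:
            f = self.fish_index(fish_id)
            if np.isnan(obs[f, occ]):
                raise DataError(f"fish {fish_id} was not observed at occasion {occ}")
            obs[f, occ] = np.nan
        return GrowthPanel(
            occasions=self.occasions,
            intervals=self.intervals,
            fish_ids=self.fish_ids,
            cave_ids=self.cave_ids,
            fish_cave=self.fish_cave,
            first=self.first,
            last=self.last,
            obs=obs,
            days=self.days,
            temp=self.temp,
            center_size=self.center_size,
            center_temp=self.center_temp,
            meta=dict(self.meta, holdouts=list(holdouts)),
        )


def build_panel(
    captures: Sequence[CaptureRecord],
    temperatures: Sequence[TemperatureRecord],
    occasions: Sequence[Occasion],
    center_size: float | None = None,
    center_temp: float | None = None,
) -> GrowthPanel:
    """Assemble a :class:`GrowthPanel` from validated records.

    Interval lengths default to the nominal-date day counts; where a fish was
    captured on both endpoints of a consecutive-occasion transition and both
    records carry actual dates, the actual-day difference is used instead.
    Centring constants default to the grand means of the observed lengths and
    observed temperatures.
    """
    if not captures:
        raise DataError("no capture records")
    occasions = list(occasions)
    T = len(occasions)
    intervals = season_intervals(occasions)

    fish_ids = sorted({r.fish_id for r in captures})
    fish_idx = {f: i for i, f in enumerate(fish_ids)}
    cave_ids = sorted({r.cave_id for r in captures} | {t.cave_id for t in temperatures})
    cave_idx = {c: i for i, c in enumerate(cave_ids)}

    F = len(fish_ids)
    obs = np.full((F, T), np.nan)
    dates: dict[tuple[int, int], dt.date] = {}
    fish_cave = np.zeros(F, dtype=int)
    for r in captures:
        f = fish_idx[r.fish_id]
        fish_cave[f] = cave_idx[r.cave_id]
        if not np.isnan(obs[f, r.occasion]):
            raise DataError(f"duplicate capture: fish {r.fish_id}, occasion {r.occasion}")
        obs[f, r.occasion] = r.fork_length_mm
        if r.capture_date is not None:
            dates[(f, r.occasion)] = r.capture_date

    observed = ~np.isnan(obs)
    if not observed.any(axis=1).all():
        raise DataError("fish with zero observations in panel")
    first = observed.argmax(axis=1)
    last = T - 1 - observed[:, ::-1].argmax(axis=1)

    nominal_days = np.array([iv.n_days for iv in intervals], dtype=float)
    days = np.tile(nominal_days, (F, 1))
    for (f, occ), date in dates.items():
        nxt = dates.get((f, occ + 1))
        if nxt is not None:
            days[f, occ] = interval_days(date, nxt)

    temp = np.full((len(cave_ids), T - 1), np.nan)
    cell_year_season = {(iv.year, iv.season): k for k, iv in enumerate(intervals)}
    covered = np.zeros_like(temp, dtype=bool)
    for t in temperatures:
        key = (t.year, t.season)
        if key not in cell_year_season:
            continue  # outside the occasion span; harmless
        k = cell_year_season[key]
        covered[cave_idx[t.cave_id], k] = True
        if t.mean_temp_C is not None:
            temp[cave_idx[t.cave_id], k] = t.mean_temp_C
    if not covered.all():
        c, k = np.argwhere(~covered)[0]
        iv = intervals[k]
        raise DataError(
            f"temperature grid does not cover the occasion span: no record for "
            f"cave {cave_ids[c]}, year {iv.year}, season {iv.season}"
        )

    if center_size is None:
        center_size = float(np.nanmean(obs))
    if center_temp is None:
        if np.isnan(temp).all():
            raise DataError("no observed temperatures to centre on")
        center_temp = float(np.nanmean(temp))
    if not (np.isfinite(center_size) and np.isfinite(center_temp)):
        raise DataError("centring constants must be finite")

    return GrowthPanel(
        occasions=occasions,
        intervals=intervals,
        fish_ids=fish_ids,
        cave_ids=cave_ids,
        fish_cave=fish_cave,
        first=first,
        last=last,
        obs=obs,
        days=days,
        temp=temp,
        center_size=center_size,
        center_temp=center_temp,
    )


def load_panel(
    captures_path: str | Path,
    temperatures_path: str | Path,
    **kwargs,
) -> GrowthPanel:
    """Read both CSV inputs and build the panel in one call."""
    captures, occasions = read_captures(captures_path)
    temps = read_temperatures(temperatures_path)
    return build_panel(captures, temps, occasions=occasions, **kwargs)
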