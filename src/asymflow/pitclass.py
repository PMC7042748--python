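"""Spawning-season movement classification from PIT-antenna detections.

Mature lake-tagged fish detected on in-stream antennae during a spawning
window (1 November - 28 February) are classed as inflow-only (IO),
outflow-only (OO) or both-streams (B).  Fish detected only outside every
window are excluded, as are fish whose estimated fork length at the window
median date falls below the maturity threshold (mean FL of visibly mature
fish minus one standard deviation).  Only the upper-outflow antennae count
toward the IO/OO/B classes; a lower-outflow antenna may be registered for
catchment-exchange reporting but is ignored by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

from .growthgdd import GrowthModel, TemperatureSeries, degree_days, predict_fl

CLASS_IO = "IO"
CLASS_OO = "OO"
CLASS_B = "B"
EXCLUDED_OUTSIDE = "excluded_outside_window"
EXCLUDED_IMMATURE = "excluded_immature"

INFLOW = "inflow"
OUTFLOW_UPPER = "outflow_upper"
OUTFLOW_LOWER = "outflow_lower"


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AntennaSite:
    antenna: str
    stream: str  # inflow | outflow_upper | outflow_lower
    distance_from_lake_m: float = 0.0

    def __post_init__(self) -> None:
        if self.stream not in (INFLOW, OUTFLOW_UPPER, OUTFLOW_LOWER):
            raise ValueError(f"unknown stream {self.stream!r}")


@dataclass(frozen=True)
class SpawningWindow:
    """One spawning season, 1 Nov through 28 Feb inclusive (leap day out)."""

    season: str
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")

    @classmethod
    def for_season(cls, start_year: int) -> "SpawningWindow":
        return cls(
            season=f"{start_year}-{start_year + 1}",
            start=date(start_year, 11, 1),
            end=date(start_year + 1, 2, 28),
        )

    def contains(self, ts: datetime) -> bool:
        d = ts.date()
        return self.start <= d <= self.end

    @property
    def median_date(self) -> date:
        """Mid-point of the window (day 60 of the 120-day season: 30 Dec)."""
        return self.start + (self.end - self.start) // 2


def read_detections_csv(path) -> pd.DataFrame:
    """Detections CSV with tag,antenna,timestamp columns (ISO-8601)."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["tag"] = df["tag"].astype(str)
    df["antenna"] = df["antenna"].astype(str)
    return df[["tag", "antenna", "timestamp"]]


# ---------------------------------------------------------------------------
# maturity
# ---------------------------------------------------------------------------

def maturity_threshold(mature_lengths) -> int:
    """Threshold length = round(mean - sample SD) of visibly mature fish."""
    lengths = np.asarray(list(mature_lengths), dtype=float)
    if lengths.size < 2:
        raise ValueError("need at least 2 mature lengths")
    return threshold_from_moments(float(lengths.mean()), float(lengths.std(ddof=1)))


def threshold_from_moments(mean_fl: float, sd_fl: float) -> int:
    """The mean-minus-one-SD maturity rule applied to summary moments."""
    return int(round(mean_fl - sd_fl))


def estimate_spawning_fl(
    fl_at_tagging: float,
    tagging_date: date,
    window: SpawningWindow,
    model: GrowthModel,
    temps: TemperatureSeries,
) -> float:
    """Predicted FL at the window median date from the degree-day model."""
    median = window.median_date
    if pd.Timestamp(tagging_date).date() > median:
        raise ValueError("capture date falls after the window median date")
    if pd.Timestamp(tagging_date).date() == median:
        return float(fl_at_tagging)
    dd = degree_days(temps, model.t0, tagging_date, median)
    return float(predict_fl(fl_at_tagging, dd, model))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class BehaviorRecord:
    tag: str
    season: str  # season label or "overall"
    estimated_fl: float | None
    mature: bool | None
    behavior: str  # IO | OO | B | excluded_immature | excluded_outside_window


def classify_movements(
    detections: pd.DataFrame,
    antennae: dict[str, AntennaSite],
    windows: list[SpawningWindow],
    maturity: pd.DataFrame | None = None,
    known_tags: set[str] | None = None,
) -> tuple[list[BehaviorRecord], pd.DataFrame]:
    """Classify each detected fish per season and overall.

    ``maturity``, if given, is a DataFrame indexed by (tag, season) with
    columns ``estimated_fl`` and ``mature``; fish marked immature in the
    season of detection are excluded for that season.  ``known_tags``
    restricts processing to registered fish (unknown tags are skipped).

    Returns the per-fish records (per season plus an "overall" record built
    from the union of in-window detections) and a season x stream tabulation
    with total / exclusive / both-stream counts.
    """
    inflow_ids = {a for a, s in antennae.items() if s.stream == INFLOW}
    upper_out_ids = {a for a, s in antennae.items() if s.stream == OUTFLOW_UPPER}
    if not inflow_ids or not upper_out_ids:
        raise ValueError("need at least one inflow and one upper-outflow antenna")
    class_ids = inflow_ids | upper_out_ids

    det = detections.copy()
    det["tag"] = det["tag"].astype(str)
    unknown_antenna = set(det["antenna"].astype(str)) - set(antennae)
    if unknown_antenna:
        raise KeyError(f"unregistered antenna id(s): {sorted(unknown_antenna)}")
    if known_tags is not None:
        det = det[det["tag"].isin(known_tags)]
    det = det[det["antenna"].isin(class_ids)]

    def lookup_maturity(tag: str, season: str) -> tuple[float | None, bool | None]:
        if maturity is None:
            return None, True
        try:
            row = maturity.loc[(tag, season)]
        except KeyError:
            return None, True
        return float(row["estimated_fl"]), bool(row["mature"])

    records: list[BehaviorRecord] = []
    per_season_class: dict[str, dict[str, str]] = {w.season: {} for w in windows}
    overall_streams: dict[str, set[str]] = {}
    any_in_window: set[str] = set()

    for tag, sub in det.groupby("tag", sort=True):
        tag = str(tag)
        dates = sub["timestamp"].dt.date
        seasons_seen = False
        for w in windows:
            in_w = sub[(dates >= w.start) & (dates <= w.end)]
            if in_w.empty:
                continue
            seasons_seen = True
            any_in_window.add(tag)
            streams = {antennae[a].stream for a in in_w["antenna"]}
            est_fl, mature = lookup_maturity(tag, w.season)
            if mature is False:
                behavior = EXCLUDED_IMMATURE
            elif streams == {INFLOW}:
                behavior = CLASS_IO
            elif streams == {OUTFLOW_UPPER}:
                behavior = CLASS_OO
            else:
                behavior = CLASS_B
            records.append(BehaviorRecord(tag, w.season, est_fl, mature, behavior))
            per_season_class[w.season][tag] = behavior
            if behavior in (CLASS_IO, CLASS_OO, CLASS_B):
                overall_streams.setdefault(tag, set()).update(streams)
        if not seasons_seen:
            records.append(
                BehaviorRecord(tag, "overall", None, None, EXCLUDED_OUTSIDE)
            )

    overall_class: dict[str, str] = {}
    for tag, streams in overall_streams.items():
        if streams == {INFLOW}:
            overall_class[tag] = CLASS_IO
        elif streams == {OUTFLOW_UPPER}:
            overall_class[tag] = CLASS_OO
        else:
            overall_class[tag] = CLASS_B
    for tag, behavior in overall_class.items():
        records.append(BehaviorRecord(tag, "overall", None, None, behavior))

    rows = []
    season_maps = dict(per_season_class)
    season_maps["overall"] = overall_class
    for season, cmap in season_maps.items():
        io = sum(1 for b in cmap.values() if b == CLASS_IO)
        oo = sum(1 for b in cmap.values() if b == CLASS_OO)
        both = sum(1 for b in cmap.values() if b == CLASS_B)
        rows.append(
            {
                "season": season,
                "stream": "outflow_upper",
                "total": oo + both,
                "exclusive": oo,
                "both": both,
            }
        )
        rows.append(
            {
                "season": season,
                "stream": "inflow",
                "total": io + both,
                "exclusive": io,
                "both": both,
            }
        )
    tabulation = pd.DataFrame(rows)
    return records, tabulation


# ---------------------------------------------------------------------------
# nocturnality
# ---------------------------------------------------------------------------

def nocturnal_fraction(detections: pd.DataFrame, solar: pd.DataFrame) -> float:
    """Fraction of detections between that date's sunset and next sunrise.

    ``solar`` has a date column plus ``sunset``/``sunrise`` times (HH:MM).
    A detection at clock time t counts as nocturnal when t >= sunset or
    t < sunrise (sunrise belonging to the morning after the labelled date's
    sunset).  Every detection date must have a solar entry.
    """
    sol = solar.copy()
    sol["date"] = pd.to_datetime(sol["date"]).dt.date
    table = {
        r.date: (
            _parse_time(r.sunset),
            _parse_time(r.sunrise),
        )
        for r in sol.itertuples()
    }
    ts = pd.to_datetime(detections["timestamp"])
    n_nocturnal = 0
    for t in ts:
        d = t.date()
        if d not in table:
            raise KeyError(f"no solar entry for {d}")
        sunset, sunrise = table[d]
        clock = t.time()
        # after sunset tonight, or before this morning's sunrise
        if clock >= sunset or clock < sunrise:
            n_nocturnal += 1
    return n_nocturnal / len(ts) if len(ts) else float("nan")


def _parse_time(value) -> time:
    if isinstance(value, time):
        return value
    return datetime.strptime(str(value), "%H:%M").time()


def default_solar_table(start: date, end: date, sunset="17:00", sunrise="08:00") -> pd.DataFrame:
    """Constant winter sunset/sunrise table spanning [start, end]."""
    days = pd.date_range(start, end, freq="D")
    return pd.DataFrame(
        {"date": days.strftime("%Y-%m-%d"), "sunset": sunset, "sunrise": sunrise}
    )
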