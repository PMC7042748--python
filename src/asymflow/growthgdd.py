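"""Growing-degree-day growth model for lake-feeding trout.

Fish growth between a tagging measurement and a later date is modelled as

    FL2 = FL1 + (a * ln(FL1) + b) * DD_T0

where DD_T0 is the sum of daily mean temperatures above a base temperature
T0 over the interval (growing degree days).  The log transform of initial
fork length reflects the von Bertalanffy-style slowdown of growth per
degree-day with size.  Calibration regresses observed growth-per-degree-day
on ln(FL1) by OLS for each candidate T0 on a grid (default 0-12 degC in
1 degC steps) and keeps the T0 that maximizes R-squared, breaking ties
toward the lower base temperature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

DEFAULT_T0_GRID: tuple[float, ...] = tuple(float(t) for t in range(13))
DEFAULT_MAX_GAP_FRACTION = 0.05


# ---------------------------------------------------------------------------
# temperature series
# ---------------------------------------------------------------------------

class TemperatureSeries:
    """Daily mean water temperatures, indexed by date.

    Accepts a pandas Series indexed by datetime-like values; sub-daily input
    is aggregated to daily arithmetic means.  Internal gaps are linearly
    interpolated as long as they make up no more than ``max_gap_fraction`` of
    the requested evaluation window (checked at query time).
    """

    def __init__(self, series: pd.Series):
        s = pd.Series(series).dropna()
        if s.empty:
            raise ValueError("temperature series is empty")
        idx = pd.to_datetime(s.index)
        s = pd.Series(s.to_numpy(dtype=float), index=idx).sort_index()
        daily = s.groupby(s.index.normalize()).mean()
        if not np.isfinite(daily.to_numpy()).all():
            raise ValueError("temperatures must be finite")
        self._daily = daily

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        df = pd.read_csv(path)
        return cls(pd.Series(df["mean_c"].to_numpy(), index=pd.to_datetime(df["date"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"date": self._daily.index.strftime("%Y-%m-%d"), "mean_c": self._daily.to_numpy()}
        ).to_csv(path, index=False)

    @property
    def daily(self) -> pd.Series:
        return self._daily.copy()

    def window(self, date1, date2, max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION) -> pd.Series:
        """Daily means for the (date1, date2] interval, gaps interpolated."""
        d1 = pd.Timestamp(date1).normalize()
        d2 = pd.Timestamp(date2).normalize()
        if d2 <= d1:
            raise ValueError("date2 must be after date1")
        wanted = pd.date_range(d1 + timedelta(days=1), d2, freq="D")
        have = self._daily.reindex(wanted)
        n_missing = int(have.isna().sum())
        if n_missing:
            if n_missing / len(wanted) > max_gap_fraction:
                raise ValueError(
                    f"temperature series missing {n_missing}/{len(wanted)} days "
                    f"in ({d1.date()}, {d2.date()}]"
                )
            have = have.interpolate(limit_direction="both")
        return have


def degree_days(
    series: TemperatureSeries,
    t0: float,
    date1,
    date2,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> float:
    """Growing degree days: sum over days in (date1, date2] of max(0, T - t0)."""
    temps = series.window(date1, date2, max_gap_fraction=max_gap_fraction)
    return float(np.clip(temps.to_numpy() - t0, 0.0, None).sum())


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------

@dataclass
class GrowthObservation:
    tag: str
    fl1: float
    fl2_obs: float
    date1: date
    date2: date

    def __post_init__(self) -> None:
        self.date1 = pd.Timestamp(self.date1).date()
        self.date2 = pd.Timestamp(self.date2).date()
        if self.date2 <= self.date1:
            raise ValueError(f"{self.tag}: recapture date must follow tagging date")
        if self.fl1 <= 0:
            raise ValueError(f"{self.tag}: FL1 must be positive")


@dataclass
class GrowthModel:
    """Fitted growth law: growth per degree-day = a * ln(FL1) + b above T0."""

    a: float
    b: float
    t0: float
    r_squared: float
    n_obs: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GrowthModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def observations_from_csv(path) -> list[GrowthObservation]:
    """Read capture pairs from a CSV with tag,fl1,fl2,date1,date2 columns."""
    df = pd.read_csv(path)
    return [
        GrowthObservation(
            tag=str(r.tag), fl1=float(r.fl1), fl2_obs=float(r.fl2),
            date1=r.date1, date2=r.date2,
        )
        for r in df.itertuples()
    ]


def fit_growth_model(
    observations: list[GrowthObservation],
    series: TemperatureSeries,
    t0_grid: tuple[float, ...] = DEFAULT_T0_GRID,
) -> GrowthModel:
    """Calibrate (a, b, T0) from tag/recapture pairs.

    For every T0 candidate, growth-per-degree-day (FL2-FL1)/DD is regressed
    on ln(FL1) by least squares weighted by DD^2 — equivalently, observed
    growth is regressed on (DD * ln FL1, DD) without an intercept.  The
    weighting reflects that measurement noise is additive on length, so the
    per-degree-day response has variance proportional to 1/DD^2; an
    unweighted fit lets short noisy intervals dominate and systematically
    drags the selected base temperature low.  The candidate minimizing the
    weighted residual sum of squares (maximal growth-scale R-squared) wins,
    ties broken toward the smaller T0.  The reported ``r_squared`` is on the
    growth-per-degree-day scale, the scale on which the calibration is
    usually quoted.  Observations whose DD is zero at a candidate are
    dropped for that candidate only (with a warning); a candidate where
    fewer than three observations survive is excluded from the search.
    """
    if len(observations) < 3:
        raise ValueError("need at least 3 observations")
    if not t0_grid:
        raise ValueError("t0 grid is empty")
    grid = sorted(t0_grid)

    best: GrowthModel | None = None
    best_score = -np.inf
    for t0 in grid:
        dd = np.array([degree_days(series, t0, o.date1, o.date2) for o in observations])
        keep = dd > 0
        if not keep.all():
            warnings.warn(
                f"T0={t0}: dropped {int((~keep).sum())} observation(s) with zero "
                "degree-days",
                stacklevel=2,
            )
        if keep.sum() < 3:
            continue
        x = np.log([o.fl1 for o, k in zip(observations, keep) if k])
        growth = np.array(
            [(o.fl2_obs - o.fl1) for o, k in zip(observations, keep) if k]
        )
        d = dd[keep]
        if np.allclose(x, x[0]):
            continue  # ln(FL1) constant: slope unidentifiable
        design = np.column_stack([d * x, d])
        coef, *_ = np.linalg.lstsq(design, growth, rcond=None)
        resid = growth - design @ coef
        ss_tot = float(((growth - growth.mean()) ** 2).sum())
        score = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
        # R^2 on the per-degree-day scale (the conventional reporting scale)
        y = growth / d
        y_hat = coef[0] * x + coef[1]
        ss_tot_y = float(((y - y.mean()) ** 2).sum())
        r2_y = 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot_y if ss_tot_y > 0 else 0.0
        if score > best_score + 1e-12:
            best_score = score
            best = GrowthModel(
                a=float(coef[0]), b=float(coef[1]), t0=float(t0),
                r_squared=max(0.0, r2_y), n_obs=int(keep.sum()),
            )
    if best is None:
        raise ValueError("no T0 candidate retained enough observations")
    return best


def predict_fl(fl1: float, dd: float, model: GrowthModel) -> float:
    """Predicted fork length after ``dd`` degree-days of growth."""
    if fl1 <= 0:
        raise ValueError("FL1 must be positive")
    if dd < 0:
        raise ValueError("degree-days must be non-negative")
    return fl1 + (model.a * np.log(fl1) + model.b) * dd
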