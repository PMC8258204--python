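"""Discrete (yearly) life tables and fecundity schedules.

Ages are integer years with age 0 the year of birth.  Survivorship
``l_x`` is the probability of being alive at the start of age ``x``;
remaining expectancy uses trapezoid person-years,
``e_x = sum_{y>=x} (l_y + l_{y+1})/2 / l_x``, and ``T_x = l_x * e_x`` is
the expected person-years lived above age ``x``.

Fecundity ``m_x`` is births per female-year at age ``x``, estimated as
births to females of age ``x`` divided by female-years at that age with
a *known* birth status; female-years in which the female was not
observed (birth status unknowable) are excluded from both numerator and
denominator.  Ages ``B`` and ``M`` bracket the reproductive span: the
ages by which 5% and 95% of cumulative fecundity have been realised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from postrepro import mortality
from postrepro.mortality import MortalityParams

__all__ = [
    "LifeTable",
    "FecunditySchedule",
    "lx_from_draws",
    "estimate_mx",
    "ages_B_M",
    "lifespan_summaries",
]


def _ex_from_lx(lx: np.ndarray) -> np.ndarray:
    """Trapezoid remaining expectancy; NaN where l_x = 0."""
    l_ext = np.append(lx, 0.0)
    person_years = 0.5 * (l_ext[:-1] + l_ext[1:])
    Tx = np.cumsum(person_years[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), np.nan)
    return ex


@dataclass
class LifeTable:
    """Age-indexed survivorship, remaining expectancy and person-years."""

    ages: np.ndarray
    lx: np.ndarray
    ex: np.ndarray
    Tx: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, int)
        self.lx = np.asarray(self.lx, float)
        self.ex = np.asarray(self.ex, float)
        self.Tx = np.asarray(self.Tx, float)
        if self.lx[0] <= 0:
            raise ValueError("l_0 must be positive")
        if np.any(np.diff(self.lx) > 1e-12):
            raise ValueError("l_x must be nonincreasing")

    @classmethod
    def from_lx(cls, ages: Sequence[int], lx: Sequence[float]) -> "LifeTable":
        ages = np.asarray(ages, int)
        lx = np.asarray(lx, float) / float(np.asarray(lx, float)[0])
        ex = _ex_from_lx(lx)
        Tx = np.where(np.isnan(ex), 0.0, lx * np.nan_to_num(ex))
        return cls(ages=ages, lx=lx, ex=ex, Tx=Tx)

    @classmethod
    def from_params(cls, params: MortalityParams, max_age: int = 120) -> "LifeTable":
        ages = np.arange(max_age + 1)
        return cls.from_lx(ages, mortality.survivorship(params, ages.astype(float)))

    def at(self, age: int) -> tuple[float, float, float]:
        """(l_x, e_x, T_x) at an integer age."""
        i = int(np.searchsorted(self.ages, age))
        if i >= len(self.ages) or self.ages[i] != age:
            raise KeyError(f"age {age} not in table")
        return float(self.lx[i]), float(self.ex[i]), float(self.Tx[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "l_x": self.lx, "e_x": self.ex, "T_x": self.Tx}
        )


@dataclass
class FecunditySchedule:
    """Age-specific fecundity with its estimation bookkeeping.

    ``mx`` is NaN at ages with no known-status female-years; those ages
    carry no information and are excluded from cumulative sums.
    """

    ages: np.ndarray
    mx: np.ndarray
    births: Optional[np.ndarray] = None
    at_risk: Optional[np.ndarray] = None
    unknown: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, int)
        self.mx = np.asarray(self.mx, float)
        if np.any(self.mx[np.isfinite(self.mx)] < 0):
            raise ValueError("m_x must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        d = {"age": self.ages, "m_x": self.mx}
        if self.births is not None:
            d.update(births=self.births, at_risk=self.at_risk, unknown=self.unknown)
        return pd.DataFrame(d)


def lx_from_draws(draws, sex: str, ages: Sequence[int]) -> pd.DataFrame:
    """Pointwise survivorship envelope over posterior draws.

    ``draws`` is a PosteriorDraws (anything exposing
    ``survivorship(sex, ages) -> (n_draws, n_ages)``) or a list of them,
    e.g. one per unknown-sex permutation; lists are pooled before the
    quantiles are taken.  Returns a frame with columns
    ``age, median, lo, hi`` (2.5% and 97.5%).
    """
    ages = np.asarray(ages, float)
    if not isinstance(draws, (list, tuple)):
        draws = [draws]
    if not draws:
        raise ValueError("no posterior draws given")
    curves = np.vstack([d.survivorship(sex, ages) for d in draws])
    if curves.size == 0:
        raise ValueError("empty posterior draws")
    med, lo, hi = np.nanpercentile(curves, [50.0, 2.5, 97.5], axis=0)
    return pd.DataFrame({"age": ages.astype(int), "median": med, "lo": lo, "hi": hi})


def estimate_mx(birth_records: pd.DataFrame) -> FecunditySchedule:
    """Estimate the fecundity schedule from yearly female birth records.

    ``birth_records`` has one row per female-year with columns ``age``
    and ``status`` in {"birth", "no_birth", "unknown"}.  Only
    known-status female-years enter the estimate; m_x = births(x) /
    known-status female-years(x).
    """
    if not len(birth_records):
        raise ValueError("no birth records")
    rec = birth_records
    known = rec[rec["status"] != "unknown"]
    if not len(known):
        raise ValueError("no female-years with known birth status")
    ages = np.arange(int(rec["age"].min()), int(rec["age"].max()) + 1)
    births = (
        known[known["status"] == "birth"].groupby("age").size()
        .reindex(ages, fill_value=0).to_numpy()
    )
    at_risk = known.groupby("age").size().reindex(ages, fill_value=0).to_numpy()
    unknown = (
        rec[rec["status"] == "unknown"].groupby("age").size()
        .reindex(ages, fill_value=0).to_numpy()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = np.where(at_risk > 0, births / np.where(at_risk > 0, at_risk, 1), np.nan)
    return FecunditySchedule(ages=ages, mx=mx, births=births,
                             at_risk=at_risk, unknown=unknown)


def ages_B_M(
    schedule: FecunditySchedule, low: float = 0.05, high: float = 0.95
) -> tuple[int, int]:
    """Ages by which fractions ``low`` and ``high`` of fecundity accrue.

    The cumulative share F(x) = sum_{y<=x} m_y / sum_y m_y runs over
    ages with defined m_x; B and M are the smallest integer ages with
    F >= low and F >= high respectively.
    """
    ok = np.isfinite(schedule.mx)
    total = schedule.mx[ok].sum()
    if total <= 0:
        raise ValueError("fecundity schedule is all zero")
    cum = np.cumsum(np.where(ok, schedule.mx, 0.0)) / total
    B = int(schedule.ages[np.searchsorted(cum, low - 1e-12)])
    M = int(schedule.ages[np.searchsorted(cum, high - 1e-12)])
    return B, M


def lifespan_summaries(table: LifeTable) -> tuple[float, float]:
    """(average life span, 90% life span) from a life table.

    Average life span is the expected remaining life at birth (e_0);
    the 90% life span is the age by which 90% of a cohort has died,
    i.e. the first age where l_x falls to 0.1, linearly interpolated
    between table rows.
    """
    average = float(table.ex[0])
    lx, ages = table.lx, table.ages.astype(float)
    idx = np.nonzero(lx <= 0.1)[0]
    if len(idx) == 0:
        warnings.warn("l_x never reaches 0.1 within the table; "
                      "returning the last tabulated age")
        return average, float(ages[-1])
    i = int(idx[0])
    if i == 0 or lx[i] == 0.1:
        return average, float(ages[i])
    # interpolate within the year in which l_x crosses 0.1
    frac = (lx[i - 1] - 0.1) / (lx[i - 1] - lx[i])
    return average, float(ages[i - 1] + frac * (ages[i] - ages[i - 1]))
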