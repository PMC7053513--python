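"""Growth physiology: rates, yields and fold changes from time courses.

Specific growth rate mu is the slope of ln(biomass) against time over a
user-chosen exponential window; yields are concentration differences over
the same interval.  During balanced exponential growth the identity
q_s = 1000 * mu / Y_X/S links the specific glucose uptake rate
(mmol gCDW^-1 h^-1) to the biomass yield (gCDW mol^-1).  Fold changes are
reported with half-up rounding to one decimal, matching how such ratios are
conventionally printed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from osmoflux.model import _data_path

PRODUCTS = ("acetate", "lactate", "pyruvate", "succinate", "oxoglutarate")


@dataclass
class GrowthTimecourse:
    """Concentration time series of one cultivation condition.

    time in h, biomass in gCDW/L (any proportional unit works for mu),
    glucose and products in mmol/L.
    """

    time: np.ndarray
    biomass: np.ndarray
    glucose: np.ndarray
    products: dict[str, np.ndarray] = field(default_factory=dict)
    condition: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.products = {
            k: np.asarray(v, dtype=float) for k, v in self.products.items()
        }
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name, arr in [("biomass", self.biomass), ("glucose", self.glucose)] + list(
            self.products.items()
        ):
            if len(arr) != len(self.time):
                raise ValueError(f"{name}: length mismatch with time")
            if np.any(arr < 0):
                raise ValueError(f"{name}: negative concentration")


@dataclass
class GrowthRateFit:
    mu: float
    r_squared: float
    n_points: int


@dataclass
class PhysiologySummary:
    mu: float
    yield_biomass: float  # Y_X/S, gCDW per mol glucose
    q_s: float  # mmol glucose per gCDW per h
    product_yields: dict[str, float]  # Y_P/S, mmol per mol glucose
    condition: float = 0.0


def _window_mask(time: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(time, dtype=bool)
    t0, t1 = window
    return (time >= t0) & (time <= t1)


def growth_rate(
    tc: GrowthTimecourse, window: tuple[float, float] | None = None
) -> GrowthRateFit:
    """Least-squares slope of ln(biomass) vs time over the exponential window.

    The window is explicit user input (mid-exponential phase chosen by
    inspection); no automatic phase detection is attempted.
    """
    mask = _window_mask(tc.time, window)
    if mask.sum() < 3:
        raise ValueError("window too small: need >= 3 points")
    biomass = tc.biomass[mask]
    if np.any(biomass <= 0):
        raise ValueError("non-positive biomass inside the window")
    res = stats.linregress(tc.time[mask], np.log(biomass))
    return GrowthRateFit(
        mu=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=int(mask.sum()),
    )


def yields(
    tc: GrowthTimecourse, window: tuple[float, float] | None = None
) -> PhysiologySummary:
    """Biomass and product yields on glucose over the window.

    Y_X/S = delta biomass / delta glucose (gCDW/mol), Y_P/S in mmol/mol,
    q_s = 1000 * mu / Y_X/S assuming balanced exponential growth.
    """
    mask = _window_mask(tc.time, window)
    if mask.sum() < 2:
        raise ValueError("window too small: need >= 2 points")
    idx = np.where(mask)[0]
    first, last = idx[0], idx[-1]
    consumed_mmol = tc.glucose[first] - tc.glucose[last]
    if consumed_mmol <= 0:
        raise ValueError("no glucose consumed over the window")
    d_biomass = tc.biomass[last] - tc.biomass[first]
    y_xs = d_biomass / (consumed_mmol / 1000.0)
    mu = growth_rate(tc, window).mu
    product_yields = {}
    for name, arr in tc.products.items():
        formed = arr[last] - arr[first]
        product_yields[name] = 1000.0 * formed / consumed_mmol
    return PhysiologySummary(
        mu=mu,
        yield_biomass=y_xs,
        q_s=1000.0 * mu / y_xs,
        product_yields=product_yields,
        condition=tc.condition,
    )


def fold_change(a: float, b: float) -> float:
    """a/b with half-up rounding to one decimal (62.6/5.8 = 10.793 -> 10.8)."""
    if b == 0:
        raise ZeroDivisionError("fold change denominator is zero")
    ratio = Decimal(repr(a)) / Decimal(repr(b))
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def load_physiology_table(path: str | Path | None = None) -> pd.DataFrame:
    """The printed physiological reference table (mu, yields, rates, AEC) for
    cultivations at 0 to 1.8 M NaCl, as a tidy DataFrame."""
    path = Path(path) if path is not None else _data_path("physiology_table.csv")
    df = pd.read_csv(path)
    return df


def table_value(
    df: pd.DataFrame, parameter: str, condition: float
) -> tuple[float, float | None]:
    """(value, sd) of one parameter at one NaCl molarity."""
    row = df[(df.parameter == parameter) & (df.condition_M == condition)]
    if row.empty:
        raise KeyError(f"{parameter} at {condition} M not in table")
    sd = row.iloc[0]["sd"]
    return float(row.iloc[0]["value"]), (None if pd.isna(sd) else float(sd))
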